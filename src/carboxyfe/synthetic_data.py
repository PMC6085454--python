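"""Synthetic fixtures: culture kinetics, paired genomes, spectrum presets.

Three generators make every analysis stage testable without downloads:

* :func:`simulate_culture` — forward-Euler culture trajectories for a
  CO-oxidizing, Fe(III)-reducing thermophile.  The noise-free signal obeys
  the catabolic electron ledger ``4*d(acetate) + 2*d(CO oxidized) =
  d(Fe2+) + 2*d(H2)`` at every step by construction, so the balance module
  can recover the configured CO partition exactly.
* :func:`generate_strain_pair` — two annotated genomes that differ by one
  strain-exclusive multiheme cytochrome gene, with a planted coo gene
  cluster (cooA | cooS-cooC | cooMKLXUH-hypA-cooF-cooS-cooC) carrying CooA
  consensus sites upstream of its two downstream operons, a configurable
  census of shared multiheme proteins, and random background CDS.
* :func:`spectrum_preset` — quadrupole-doublet models for a glauconite
  reduction series whose Fe2+ shares (2.2%, 5.7%) and siderite area (3.9%)
  are the quantities of interest; line positions and widths are
  literature-typical defaults and freely overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_screen import (GeneFeature, count_heme_motifs, reverse_complement,
                            scan_iupac)
from .mossbauer import Doublet
from .timeseries import CultureTimeseries

# =========================================================================
# culture simulation
# =========================================================================

COOA_CONSENSUS = "TGTCRNNNNNNYGACR"


@dataclass(frozen=True)
class CultureScenario:
    """Configuration of one simulated culture experiment.

    The two growth phases differ in how CO electrons are split between
    Fe(III) reduction and hydrogenogenesis (``phase1_partition`` /
    ``phase2_partition``, fractions of CO electrons going to Fe) and in the
    stoichiometric coupling of lactate catabolism to CO oxidation
    (``co_per_lactate``: mol CO oxidized per mol lactate catabolized to
    acetate).  The switch fires when the medium redox potential drops below
    ``eh_switch_mV``; Eh itself declines linearly from ``eh_initial_mV``
    toward ``eh_floor_mV`` as Fe(II) accumulates toward ``fe2_reference``.
    """

    name: str
    co_initial: float            # mmol/L-equivalent available CO
    lactate_initial: float       # mM
    fe3_initial: float           # mM microbially accessible Fe(III)
    phase1_partition: float      # fraction of CO electrons to Fe(III), phase 1
    phase2_partition: float      # same, phase 2
    eh_switch_mV: float
    eh_initial_mV: float = -90.0
    eh_floor_mV: float = -360.0
    fe2_reference: float = 27.0  # mM Fe(II) at which Eh reaches the floor
    co_per_lactate: tuple[float, float] = (30.0, 270.0)  # per phase
    acetate_yield: tuple[float, float] = (0.77, 0.254)   # acetate per lactate consumed
    lactate_per_co_assimilated: float = 0.0  # carbon-source-only lactate draw
    vmax: float = 0.55           # mM CO h-1 at unit relative cell density
    k_co: float = 5.0            # mM, Monod constant for CO
    cells_initial: float = 2e6   # cells/ml
    cells_per_electron: float = 6e5  # cells/ml per mM electron equivalent
    t_end: float = 96.0
    dt: float = 0.05
    sample_every: float = 2.0
    noise_sd: float = 0.0        # relative Gaussian noise on observed columns
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.phase1_partition, self.phase2_partition):
            if not (0.0 <= p <= 1.0):
                raise ValueError("partitions must lie in [0, 1]")
        if min(self.co_initial, self.lactate_initial, self.fe3_initial) < 0:
            raise ValueError("initial pools must be non-negative")


_SCENARIOS = {
    # Ferrihydrite + CO + lactate: two phases, phase 1 iron-reducing at the
    # canonical 13/30 CO partition and 30:1 CO:lactate coupling, phase 2
    # hydrogenogenic at 3/270 with 270:1 coupling.  Tuned so cumulative
    # lactate consumption is ~2.3 mM with ~1.1 mM acetate formed and the
    # phase switch falls near 24 h.
    "ferrihydrite_CO_lactate": CultureScenario(
        name="ferrihydrite_CO_lactate",
        co_initial=120.0, lactate_initial=2.6, fe3_initial=110.0,
        phase1_partition=13.0 / 30.0, phase2_partition=3.0 / 270.0,
        eh_switch_mV=-320.0, eh_floor_mV=-360.0, fe2_reference=27.0,
        vmax=0.19, t_end=96.0),
    # Glauconite + CO + lactate: no acetate (lactate is carbon source only),
    # a small structural-Fe(III) pool, Fe reduction driven entirely by CO and
    # ceasing on CO exhaustion; ~1.42 mM Fe(II) and ~1 mM lactate drawn.
    "glauconite_CO_lactate": CultureScenario(
        name="glauconite_CO_lactate",
        co_initial=55.0, lactate_initial=1.3, fe3_initial=2.0,
        phase1_partition=0.008, phase2_partition=0.017,
        eh_switch_mV=-200.0, eh_floor_mV=-520.0, fe2_reference=1.5,
        co_per_lactate=(1e9, 1e9), acetate_yield=(0.0, 0.0),
        lactate_per_co_assimilated=0.019, vmax=0.085, t_end=120.0),
    # Autotrophic low-Eh control: CO only, no Fe(III), pure hydrogenogenic
    # carboxydotrophy (CO + H2O -> CO2 + H2) at constant low Eh.
    "lowEh_CO_only": CultureScenario(
        name="lowEh_CO_only",
        co_initial=55.0, lactate_initial=0.0, fe3_initial=0.0,
        phase1_partition=0.0, phase2_partition=0.0,
        eh_switch_mV=0.0, eh_initial_mV=-430.0, eh_floor_mV=-430.0,
        vmax=0.45, t_end=96.0),
}


def scenario_preset(name: str) -> CultureScenario:
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid: {sorted(_SCENARIOS)}")
    return _SCENARIOS[name]


def simulate_culture(scenario: CultureScenario) -> CultureTimeseries:
    """Forward-Euler trajectory of one culture scenario.

    Per step, the CO oxidation rate is first-order in cells with a Monod
    term on CO; lactate catabolism (where active) is slaved to it by the
    phase's CO:lactate coupling; the resulting electron flux is split
    between Fe(III) (limited by the remaining accessible pool) and protons.
    Cell yield is proportional to catabolic electron flux.  Gaussian
    relative noise, when requested, is applied to the sampled columns last.
    """
    sc = scenario
    n_steps = int(round(sc.t_end / sc.dt))
    co, lac, fe3 = sc.co_initial, sc.lactate_initial, sc.fe3_initial
    ace = h2 = co2 = fe2 = 0.0
    cells = sc.cells_initial
    eh = sc.eh_initial_mV
    rows = [(0.0, cells, co, h2, co2, lac, ace, fe2, eh)]
    sample_stride = max(int(round(sc.sample_every / sc.dt)), 1)
    phase2 = eh < sc.eh_switch_mV

    for step in range(1, n_steps + 1):
        if not phase2 and eh < sc.eh_switch_mV:
            phase2 = True
        idx = 1 if phase2 else 0
        partition = sc.phase2_partition if phase2 else sc.phase1_partition
        ratio = sc.co_per_lactate[idx]
        yld = sc.acetate_yield[idx]

        r_co = sc.vmax * (cells / sc.cells_initial) * co / (co + sc.k_co)
        d_co = min(r_co * sc.dt, co)
        # lactate catabolized to acetate, slaved to CO oxidation
        d_lac_cat = 0.0
        if yld > 0 and lac > 0:
            d_lac_cat = min(d_co / ratio, lac * yld)
        # electron routing: lactate electrons must go to Fe(III)
        e_lac = 4.0 * d_lac_cat
        e_co = 2.0 * d_co
        fe_demand = e_lac + partition * e_co
        fe_used = min(fe_demand, fe3)
        if fe_used < e_lac:  # not enough iron even for lactate electrons
            d_lac_cat = fe_used / 4.0
            e_lac = fe_used
        d_h2 = (e_lac + e_co - fe_used) / 2.0

        d_lac_total = d_lac_cat / yld if yld > 0 else 0.0
        if sc.lactate_per_co_assimilated > 0:
            d_lac_total += sc.lactate_per_co_assimilated * d_co
        d_lac_total = min(d_lac_total, lac)

        co -= d_co
        lac -= d_lac_total
        ace += d_lac_cat
        co2 += d_co + d_lac_cat
        fe2 += fe_used
        fe3 -= fe_used
        h2 += d_h2
        cells += sc.cells_per_electron * (e_lac + e_co)
        span = sc.eh_floor_mV - sc.eh_initial_mV
        eh = sc.eh_initial_mV + span * min(fe2 / sc.fe2_reference, 1.0)

        if step % sample_stride == 0 or step == n_steps:
            rows.append((step * sc.dt, cells, co, h2, co2, lac, ace, fe2, eh))

    df = pd.DataFrame(rows, columns=["time_h", "cells_per_ml", "CO_mmol",
                                     "H2_mmol", "CO2_mmol", "lactate_mM",
                                     "acetate_mM", "Fe2_mM", "Eh_mV"])
    if sc.name == "glauconite_CO_lactate":
        df = df.drop(columns=["acetate_mM"])
    if sc.noise_sd > 0:
        rng = np.random.default_rng(sc.seed)
        for col in df.columns:
            if col == "time_h":
                continue
            noisy = df[col] * (1.0 + sc.noise_sd * rng.standard_normal(len(df)))
            df[col] = noisy if col == "Eh_mV" else noisy.clip(lower=0.0)
    meta = {"scenario": sc.name,
            "phase1_partition": sc.phase1_partition,
            "phase2_partition": sc.phase2_partition}
    return CultureTimeseries(df, label=sc.name, meta=meta)


# =========================================================================
# paired genomes with planted determinants
# =========================================================================

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_NO_CH = "".join(c for c in _AA_ALPHABET if c not in "CH")

_CODON_TABLE = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOP = "TAA"


@dataclass(frozen=True)
class StrainPairSpec:
    """Layout of the synthetic strain pair.

    Strain A stands for the non-iron-reducing type strain, strain B for the
    Fe(III) reducer that carries one extra multiheme cytochrome gene of
    ``unique_multiheme_hemes`` heme-binding motifs (disabled by setting it
    to 0).  ``shared_multiheme_hemes`` lists the heme counts of the
    multiheme proteins planted identically in both strains.
    """

    genome_length: int = 120_000
    gc_fraction: float = 0.4914
    n_background_cds: int = 25
    shared_multiheme_hemes: tuple[int, ...] = tuple(
        [3, 3, 4, 4, 4, 5, 5, 5, 6, 6, 6, 7, 7, 8, 8,
         8, 9, 9, 10, 10, 11, 11, 12, 12, 13, 13, 14, 15, 15, 16])
    unique_multiheme_hemes: int = 17
    coo_site_count: int = 2
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValueError("GC fraction must lie in (0, 1)")


#: Gene order of the planted coo cluster, grouped by operon.
COO_OPERON_STRUCTURE = (
    ("cooA",),
    ("cooS-1", "cooC-1"),
    ("cooM", "cooK", "cooL", "cooX", "cooU", "cooH", "hypA",
     "cooF", "cooS-2", "cooC-2"),
)
_COO_GENE_AA_LENGTHS = {
    "cooA": 220, "cooS-1": 630, "cooC-1": 250, "cooM": 310, "cooK": 150,
    "cooL": 180, "cooX": 130, "cooU": 160, "cooH": 360, "hypA": 110,
    "cooF": 170, "cooS-2": 640, "cooC-2": 255,
}


@dataclass
class SyntheticStrain:
    name: str
    genome: str
    features: list[GeneFeature]
    proteome: dict[str, str]


@dataclass
class StrainPair:
    strain_a: SyntheticStrain
    strain_b: SyntheticStrain
    truth: dict = field(default_factory=dict)


_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def random_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """A uniform random genome at the given GC fraction (fast, seeded)."""
    return _random_dna(np.random.default_rng(seed), length, gc)


def _random_protein(rng: np.random.Generator, length: int,
                    alphabet: str = _AA_ALPHABET) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _multiheme_protein(rng: np.random.Generator, n_hemes: int) -> str:
    """A protein with exactly ``n_hemes`` CXXCH motifs.

    Linkers exclude C and H, so the strict and extended censuses both count
    exactly the planted motifs.
    """
    parts = [_random_protein(rng, int(rng.integers(25, 36)), _AA_NO_CH)]
    for _ in range(n_hemes):
        spacer = _random_protein(rng, 2, _AA_NO_CH)
        parts.append(f"C{spacer}CH")
        parts.append(_random_protein(rng, int(rng.integers(25, 36)), _AA_NO_CH))
    return "".join(parts)


def _reverse_translate(rng: np.random.Generator, protein: str, gc: float) -> str:
    codons = []
    for aa in protein:
        options = _CODON_TABLE[aa]
        weights = np.array([
            np.prod([gc / 2 if b in "GC" else (1 - gc) / 2 for b in codon])
            for codon in options])
        weights = weights / weights.sum()
        codons.append(options[int(rng.choice(len(options), p=weights))])
    return "ATG" + "".join(codons) + _STOP


def _translate(cds: str) -> str:
    inv = {codon: aa for aa, codons in _CODON_TABLE.items() for codon in codons}
    aas = []
    for i in range(3, len(cds) - 3, 3):
        aas.append(inv[cds[i:i + 3]])
    return "".join(aas)


def _sample_consensus(rng: np.random.Generator, pattern: str) -> str:
    from .genome_screen import IUPAC_CODES
    return "".join(rng.choice(list(IUPAC_CODES[c])) for c in pattern)


def _clean_intergenic(rng: np.random.Generator, length: int, gc: float,
                      pattern: str = COOA_CONSENSUS, tries: int = 50) -> str:
    """Intergenic DNA free of consensus matches (rejection sampling).

    Used only inside the planted coo neighborhood; elsewhere random
    consensus hits are deliberately left in for the upstream-window filter
    to deal with.
    """
    for _ in range(tries):
        seq = _random_dna(rng, length, gc)
        if not scan_iupac(seq, pattern):
            return seq
    raise RuntimeError("could not sample consensus-free intergenic DNA")


def mutate_sequence(seq: str, rate: float, seed: int) -> str:
    """I.i.d. substitutions at the given per-base rate (always to a
    different base)."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    sites = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.array(list("ACGT"), dtype="S1")
    for i in sites:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def generate_strain_pair(spec: StrainPairSpec = StrainPairSpec()) -> StrainPair:
    """Build the annotated strain pair with planted determinants.

    Both strains carry the same coo cluster (with CooA consensus instances
    planted upstream of its two downstream operons), the same shared
    multiheme genes and the same background CDS; strain B additionally
    carries one exclusive multiheme gene.  Deterministic under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction

    # --- shared gene payloads -------------------------------------------
    coo_proteins = {g: _random_protein(rng, _COO_GENE_AA_LENGTHS[g])
                    for op in COO_OPERON_STRUCTURE for g in op}
    shared_multi = [(f"mh{i:02d}", _multiheme_protein(rng, h))
                    for i, h in enumerate(spec.shared_multiheme_hemes, 1)]
    background = []
    while len(background) < spec.n_background_cds:
        prot = _random_protein(rng, int(rng.integers(120, 320)))
        if count_heme_motifs(prot, "extended").count >= 3:
            continue  # keep the multiheme census unambiguous
        background.append((f"bg{len(background) + 1:02d}", prot))
    unique_protein = (_multiheme_protein(rng, spec.unique_multiheme_hemes)
                      if spec.unique_multiheme_hemes > 0 else None)

    # --- genome layout: a list of (kind, payload) segments ---------------
    def build_strain(name: str, tag: str, include_unique: bool) -> tuple[SyntheticStrain, dict]:
        lrng = np.random.default_rng(spec.seed + (1 if include_unique else 0) + 100)
        segments: list[str] = []
        features: list[GeneFeature] = []
        proteome: dict[str, str] = {}
        truth: dict = {"cooA_sites": [], "coo_operons": [], "multihemes": {}}
        pos = 1  # next free 1-based coordinate
        counter = 0

        def emit_gap(length: int, clean: bool = False) -> None:
            nonlocal pos
            seq = (_clean_intergenic(lrng, length, gc) if clean
                   else _random_dna(lrng, length, gc))
            segments.append(seq)
            pos += length

        def emit_site() -> None:
            nonlocal pos
            site = _sample_consensus(lrng, COOA_CONSENSUS)
            segments.append(site)
            truth["cooA_sites"].append(pos)
            pos += len(site)

        def emit_gene(gene_name: str, protein: str, strand: str,
                      product: str) -> str:
            nonlocal pos, counter
            counter += 1
            locus = f"{tag}_{counter:04d}"
            cds = _reverse_translate(lrng, protein, gc)
            genome_seq = cds if strand == "+" else reverse_complement(cds)
            segments.append(genome_seq)
            features.append(GeneFeature(locus, name, pos, pos + len(cds) - 1,
                                        strand, "CDS", product))
            proteome[locus] = protein
            pos += len(cds)
            truth.setdefault("locus_by_name", {})[gene_name] = locus
            return locus

        # leading background half
        half = spec.n_background_cds // 2
        for bid, prot in background[:half]:
            strand = "+" if lrng.random() < 0.5 else "-"
            emit_gap(int(lrng.integers(120, 220)))
            emit_gene(bid, prot, strand, "hypothetical protein")

        # coo cluster (all plus strand, consensus-free local intergenics)
        emit_gap(200, clean=True)
        for op_index, operon in enumerate(COO_OPERON_STRUCTURE):
            if op_index > 0:
                # CooA site inside the upstream intergenic space
                emit_gap(60, clean=True)
                emit_site()
                emit_gap(50, clean=True)
            locus_ids = []
            for j, gene_name in enumerate(operon):
                if j > 0:
                    emit_gap(int(lrng.integers(5, 21)), clean=True)
                locus_ids.append(emit_gene(gene_name, coo_proteins[gene_name],
                                           "+", gene_name))
            truth["coo_operons"].append(tuple(locus_ids))
        emit_gap(200, clean=True)

        # shared multiheme genes (plus the exclusive one for strain B)
        multis = list(shared_multi)
        if include_unique and unique_protein is not None:
            multis.append(("mh_unique", unique_protein))
        for mid, prot in multis:
            emit_gap(int(lrng.integers(120, 220)))
            locus = emit_gene(mid, prot, "+" if lrng.random() < 0.5 else "-",
                              "multiheme c-type cytochrome")
            truth["multihemes"][locus] = prot.count("C") // 2  # planted CXXCH count

        # trailing background half
        for bid, prot in background[half:]:
            strand = "+" if lrng.random() < 0.5 else "-"
            emit_gap(int(lrng.integers(120, 220)))
            emit_gene(bid, prot, strand, "hypothetical protein")

        used = pos - 1
        if used > spec.genome_length:
            raise ValueError(
                f"infeasible packing: layout needs {used} bp but genome_length "
                f"is {spec.genome_length}")
        segments.append(_random_dna(lrng, spec.genome_length - used, gc))
        genome = "".join(segments)
        truth["multiheme_counts"] = {locus: count for locus, count
                                     in truth["multihemes"].items()}
        return SyntheticStrain(name, genome, features, proteome), truth

    include_b_unique = unique_protein is not None
    strain_a, truth_a = build_strain("strain_A", "SA", include_unique=False)
    strain_b, truth_b = build_strain("strain_B", "SB",
                                     include_unique=include_b_unique)
    truth = {
        "strain_a": truth_a,
        "strain_b": truth_b,
        "unique_locus_b": truth_b["locus_by_name"].get("mh_unique"),
        "unique_hemes": spec.unique_multiheme_hemes,
        "n_shared_multihemes": len(spec.shared_multiheme_hemes),
    }
    return StrainPair(strain_a, strain_b, truth)


def write_strain(strain: SyntheticStrain, outdir) -> None:
    """FASTA genome + proteome, GFF3 and TSV feature table for one strain."""
    from pathlib import Path

    from .genome_screen import write_fasta, write_feature_table, write_gff3
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta({strain.name: strain.genome}, out / f"{strain.name}.fna")
    write_fasta(strain.proteome, out / f"{strain.name}.faa")
    write_feature_table(strain.features, out / f"{strain.name}.features.tsv")
    write_gff3(strain.features, out / f"{strain.name}.gff3",
               {strain.name: len(strain.genome)})


# =========================================================================
# Mossbauer presets
# =========================================================================

# Positions/widths are literature-typical room-temperature values for
# glauconite (two Fe3+ octahedral doublets, one Fe2+ octahedral doublet) and
# siderite; only the area fractions are the quantities the presets pin down.
_PRESETS = {
    "glauconite_initial": (
        Doublet(0.35, 0.45, 0.32, 0.600, "Fe3+ octahedral silicate"),
        Doublet(0.37, 1.00, 0.32, 0.378, "Fe3+ octahedral silicate"),
        Doublet(1.12, 2.60, 0.32, 0.022, "Fe2+ octahedral silicate"),
    ),
    "glauconite_166h": (
        Doublet(0.35, 0.45, 0.32, 0.580, "Fe3+ octahedral silicate"),
        Doublet(0.37, 1.00, 0.32, 0.363, "Fe3+ octahedral silicate"),
        Doublet(1.12, 2.60, 0.32, 0.057, "Fe2+ octahedral silicate"),
    ),
    "glauconite_960h": (
        Doublet(0.35, 0.45, 0.32, 0.545, "Fe3+ octahedral silicate"),
        Doublet(0.37, 1.00, 0.32, 0.344, "Fe3+ octahedral silicate"),
        Doublet(1.12, 2.60, 0.32, 0.072, "Fe2+ octahedral silicate"),
        Doublet(1.22, 1.80, 0.32, 0.039, "siderite"),
    ),
}


def spectrum_preset(name: str) -> list[Doublet]:
    """Doublet model for one stage of the glauconite bio-reduction series.

    ``glauconite_initial`` carries 2.2% of its area in the Fe2+ doublet,
    ``glauconite_166h`` 5.7%, and ``glauconite_960h`` adds a 3.9% siderite
    doublet for four doublets total.  Areas sum to 1.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; valid: {sorted(_PRESETS)}")
    return list(_PRESETS[name])
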