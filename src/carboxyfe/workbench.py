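"""Command-line workbench tying the analysis stages together.

Every subcommand is a thin wrapper over the library; ``replay`` chains the
whole pipeline on synthetic inputs: culture simulation -> electron-balance
partitioning; spectrum presets -> simulation -> constrained fitting -> phase
fractions; strain-pair generation -> motif/operon/census/comparison screens
and ANI.  All randomness funnels through a single ``--seed``.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import click
import numpy as np
import yaml

from . import genome_screen as gs
from . import mossbauer as mb
from . import redox_balance as rb
from . import synthetic_data as sd
from .timeseries import CultureTimeseries

log = logging.getLogger("carboxyfe")


def _setup_logging(verbose: bool) -> None:
    logging.basicConfig(level=logging.DEBUG if verbose else logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def load_config(path: Optional[str]) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


@click.group()
@click.option("--verbose", is_flag=True, help="Debug logging.")
def cli(verbose: bool) -> None:
    """Electron-balance, Mossbauer and genome screens for CO-driven iron reducers."""
    _setup_logging(verbose)


@cli.command("simulate-culture")
@click.option("--scenario", default="ferrihydrite_CO_lactate",
              show_default=True, help="Scenario preset name.")
@click.option("--noise-sd", default=0.0, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def simulate_culture_cmd(scenario: str, noise_sd: float, seed: int, out: str) -> None:
    """Simulate a culture time series and write it as CSV."""
    from dataclasses import replace
    sc = replace(sd.scenario_preset(scenario), noise_sd=noise_sd, seed=seed)
    ts = sd.simulate_culture(sc)
    ts.to_csv(out)
    click.echo(f"wrote {len(ts)} time points to {out}")


@cli.command("balance")
@click.argument("csv_path", type=click.Path(exists=True))
@click.option("--breakpoint", "breakpoints", multiple=True, type=float,
              help="Phase boundary in hours (repeatable); auto-detected if omitted.")
@click.option("--out", type=click.Path(), default=None)
def balance_cmd(csv_path: str, breakpoints: tuple[float, ...],
                out: Optional[str]) -> None:
    """Compose per-phase brutto-equations and CO partitions from a CSV."""
    ts = CultureTimeseries.from_csv(csv_path)
    bps = list(breakpoints)
    if not bps:
        try:
            bps = [rb.detect_breakpoint(ts)]
        except (rb.NoDistinctPhasesError, ValueError) as err:
            log.info("no breakpoint detected (%s); using full span", err)
    report = rb.balance_report(ts, bps)
    text = json.dumps(report, indent=2)
    if out:
        Path(out).write_text(text)
    click.echo(text)


@cli.command("simulate-mossbauer")
@click.option("--preset", default="glauconite_960h", show_default=True)
@click.option("--model", "model_yaml", type=click.Path(exists=True),
              help="YAML doublet model overriding the preset.")
@click.option("--baseline", default=1e6, show_default=True)
@click.option("--noise/--no-noise", default=True, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def simulate_mossbauer_cmd(preset: str, model_yaml: Optional[str],
                           baseline: float, noise: bool, seed: int,
                           out: str) -> None:
    """Simulate a doublet spectrum and write velocity/counts columns."""
    model = (_doublets_from_yaml(model_yaml) if model_yaml
             else sd.spectrum_preset(preset))
    spec = mb.simulate_spectrum(model, baseline=baseline, noise=noise, seed=seed)
    mb.write_spectrum(spec, out)
    click.echo(f"wrote {len(spec.velocity)} channels to {out}")


def _doublets_from_yaml(path: str) -> list[mb.Doublet]:
    entries = yaml.safe_load(Path(path).read_text())
    return [mb.Doublet(e["delta"], e["splitting"], e["fwhm"], e["area"],
                       e.get("label", "")) for e in entries]


@cli.command("fit-mossbauer")
@click.argument("spectrum_path", type=click.Path(exists=True))
@click.option("--n-doublets", default=4, show_default=True)
@click.option("--shared-fwhm/--free-fwhm", default=True, show_default=True)
@click.option("--out", type=click.Path(), default=None)
def fit_mossbauer_cmd(spectrum_path: str, n_doublets: int, shared_fwhm: bool,
                      out: Optional[str]) -> None:
    """Fit quadrupole doublets to a two-column spectrum file."""
    spec = mb.read_spectrum(spectrum_path)
    fit = mb.assign_phases(mb.fit_spectrum(spec, n_doublets,
                                           shared_fwhm=shared_fwhm))
    report = _fit_report(fit)
    text = json.dumps(report, indent=2)
    if out:
        Path(out).write_text(text)
    click.echo(text)


def _fit_report(fit: mb.FitResult) -> dict:
    return {
        "shared_fwhm": fit.shared_fwhm,
        "residual_norm": fit.residual_norm,
        "baseline": fit.baseline,
        "fe2_share_percent": mb.fe2_share(fit),
        "doublets": [
            {"label": d.label, "delta_mm_s": d.delta, "splitting_mm_s": d.splitting,
             "fwhm_mm_s": d.fwhm, "area": d.area,
             "fraction": float(f),
             "errors": {k: v for k, v in d.errors.items()}}
            for d, f in zip(fit.doublets, fit.fractions)
        ],
    }


@cli.command("make-strain-pair")
@click.option("--seed", default=7, show_default=True)
@click.option("--outdir", type=click.Path(), required=True)
def make_strain_pair_cmd(seed: int, outdir: str) -> None:
    """Generate the synthetic strain pair and write FASTA/GFF3/TSV files."""
    pair = sd.generate_strain_pair(sd.StrainPairSpec(seed=seed))
    sd.write_strain(pair.strain_a, outdir)
    sd.write_strain(pair.strain_b, outdir)
    click.echo(f"wrote strain_A and strain_B under {outdir}")


@cli.command("scan-genome")
@click.argument("fasta_path", type=click.Path(exists=True))
@click.option("--pattern", default=sd.COOA_CONSENSUS, show_default=True)
@click.option("--bed-out", type=click.Path(), default=None)
def scan_genome_cmd(fasta_path: str, pattern: str, bed_out: Optional[str]) -> None:
    """Scan a genome FASTA for an IUPAC consensus on both strands."""
    hits = []
    for contig, seq in gs.read_fasta(fasta_path).items():
        hits.extend(gs.scan_iupac(seq, pattern, contig=contig))
    for h in hits:
        click.echo(f"{h.contig}\t{h.start}\t{h.strand}\t{h.matched}")
    if bed_out:
        gs.write_bed(hits, bed_out)
    click.echo(f"{len(hits)} hits")


@cli.command("heme-census")
@click.argument("proteome_path", type=click.Path(exists=True))
@click.option("--min-hemes", default=3, show_default=True)
@click.option("--spacer-policy", default="strict", show_default=True,
              type=click.Choice(["strict", "extended"]))
@click.option("--out", type=click.Path(), default=None)
def heme_census_cmd(proteome_path: str, min_hemes: int, spacer_policy: str,
                    out: Optional[str]) -> None:
    """CXXCH census of a protein FASTA; lists multiheme cytochromes."""
    proteome = gs.read_fasta(proteome_path)
    entries = gs.find_multihemes(proteome, min_hemes, spacer_policy)
    for e in entries:
        click.echo(f"{e.protein_id}\t{e.count}\t{e.length}")
    if out:
        gs.census_tsv(entries, out)
    click.echo(f"{len(entries)} multiheme proteins (>= {min_hemes} motifs)")


@cli.command("compare-strains")
@click.argument("proteome_a", type=click.Path(exists=True))
@click.argument("proteome_b", type=click.Path(exists=True))
@click.option("--min-identity", default=40.0, show_default=True)
@click.option("--min-coverage", default=70.0, show_default=True)
@click.option("--out", type=click.Path(), default=None)
def compare_strains_cmd(proteome_a: str, proteome_b: str, min_identity: float,
                        min_coverage: float, out: Optional[str]) -> None:
    """Reciprocal-best-hit comparison of two proteome FASTA files."""
    comp = gs.reciprocal_unique(gs.read_fasta(proteome_a),
                                gs.read_fasta(proteome_b),
                                min_identity, min_coverage)
    report = {
        "shared": [{"id_a": a, "id_b": b, "identity": i, "coverage": c}
                   for a, b, i, c in comp.shared],
        "unique_to_a": comp.unique_to_a,
        "unique_to_b": comp.unique_to_b,
    }
    text = json.dumps(report, indent=2)
    if out:
        Path(out).write_text(text)
    click.echo(text)


@cli.command("ani")
@click.argument("fasta_a", type=click.Path(exists=True))
@click.argument("fasta_b", type=click.Path(exists=True))
def ani_cmd(fasta_a: str, fasta_b: str) -> None:
    """Fragment-based average nucleotide identity between two genomes."""
    a = "".join(gs.read_fasta(fasta_a).values())
    b = "".join(gs.read_fasta(fasta_b).values())
    click.echo(f"ANI = {gs.ani(a, b):.2f} %")


# --- end-to-end replay ------------------------------------------------------


def replay(seed: int = 0, n_mossbauer_seeds: int = 20) -> dict:
    """Run the full synthetic pipeline and assemble one report.

    Stages: (1) simulate the ferrihydrite culture and partition its CO
    between iron reduction and hydrogenogenesis per phase; (2) simulate and
    fit the glauconite Mossbauer series, reporting Fe2+ shares and the
    siderite area; (3) generate the strain pair and run the genomic screens.
    Raises if any internal balance check fails.
    """
    rng = np.random.default_rng(seed)
    report: dict = {"seed": seed}

    # stage 1: culture + electron balance
    t0 = time.time()
    from dataclasses import replace as dc_replace
    scenario = sd.scenario_preset("ferrihydrite_CO_lactate")
    ts = sd.simulate_culture(dc_replace(scenario, seed=seed))
    try:
        bp = rb.breakpoint_from_eh(ts, scenario.eh_switch_mV)
    except (rb.NoDistinctPhasesError, ValueError):
        bp = rb.detect_breakpoint(ts)
    balance = rb.balance_report(ts, [bp])
    for phase in balance["phases"]:
        if any(abs(r) > 1e-6 for r in phase["residuals"].values()):
            raise RuntimeError(f"balance check failed in {phase['phase']}")
    report["culture"] = {"breakpoint_h": bp, **balance}
    log.info("stage culture+balance done in %.1fs", time.time() - t0)

    # stage 2: Mossbauer series
    t0 = time.time()
    moss = {}
    for preset in ("glauconite_initial", "glauconite_166h", "glauconite_960h"):
        model = sd.spectrum_preset(preset)
        fe2, siderite = [], []
        for k in range(n_mossbauer_seeds):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec = mb.simulate_spectrum(model, baseline=1e6, noise=True,
                                        seed=sub_seed)
            fit = mb.assign_phases(mb.fit_spectrum(spec, len(model)))
            fe2.append(mb.fe2_share(fit))
            siderite.append(mb.phase_fraction(fit, "siderite"))
        moss[preset] = {
            "n_seeds": n_mossbauer_seeds,
            "fe2_share_percent_mean": float(np.mean(fe2)),
            "fe2_share_percent_sd": float(np.std(fe2)),
            "siderite_percent_mean": float(np.mean(siderite)),
        }
    report["mossbauer"] = moss
    log.info("stage mossbauer done in %.1fs", time.time() - t0)

    # stage 3: genome screens
    t0 = time.time()
    pair = sd.generate_strain_pair(sd.StrainPairSpec(seed=seed + 7))
    report["genome"] = genome_screen_report(pair)
    log.info("stage genome done in %.1fs", time.time() - t0)
    return report


def genome_screen_report(pair: "sd.StrainPair") -> dict:
    """Motif/operon/census/comparison screens on a strain pair."""
    out: dict = {}
    b = pair.strain_b
    hits = gs.scan_iupac(b.genome, sd.COOA_CONSENSUS, contig=b.name)
    operons = gs.infer_operons(b.features)
    assigned = gs.assign_sites_to_operons(hits, operons)
    coo_operons = pair.truth["strain_b"]["coo_operons"]
    flagged = {op.gene_ids: [h.start for h in hs] for op, hs in assigned.items()}
    out["cooA_hits_total"] = len(hits)
    out["operons_total"] = len(operons)
    out["co_regulated_operons"] = {"..".join(k): v for k, v in flagged.items()}
    out["planted_coo_operons_recovered"] = sum(
        1 for op in coo_operons[1:] if tuple(op) in flagged)

    census_a = gs.find_multihemes(pair.strain_a.proteome)
    census_b = gs.find_multihemes(b.proteome)
    comp = gs.reciprocal_unique(pair.strain_a.proteome, b.proteome)
    unique_census = [e for e in census_b if e.protein_id in comp.unique_to_b]
    out["multihemes_strain_a"] = len(census_a)
    out["multihemes_strain_b"] = len(census_b)
    out["unique_to_a"] = comp.unique_to_a
    out["unique_to_b"] = comp.unique_to_b
    out["unique_multiheme_counts"] = {e.protein_id: e.count for e in unique_census}
    return out


@cli.command("replay")
@click.option("--seed", default=0, show_default=True)
@click.option("--config", type=click.Path(exists=True), default=None,
              help="YAML overriding replay parameters.")
@click.option("--out", type=click.Path(), default=None)
@click.option("--markdown-out", type=click.Path(), default=None)
def replay_cmd(seed: int, config: Optional[str], out: Optional[str],
               markdown_out: Optional[str]) -> None:
    """Run the end-to-end synthetic pipeline and write the JSON report."""
    cfg = load_config(config)
    report = replay(seed=cfg.get("seed", seed),
                    n_mossbauer_seeds=cfg.get("n_mossbauer_seeds", 20))
    text = json.dumps(report, indent=2)
    if out:
        Path(out).write_text(text)
    if markdown_out:
        Path(markdown_out).write_text(_markdown_report(report))
    click.echo(text)


def _markdown_report(report: dict) -> str:
    lines = ["# Synthetic pipeline replay", ""]
    for phase in report["culture"]["phases"]:
        frac = phase["fraction_fe"]
        pct = "undefined" if frac is None else f"{100 * frac:.1f}%"
        lines.append(f"- {phase['phase']}: CO to Fe(III) {pct}; "
                     f"equation `{phase['equation']}`")
    lines.append("")
    for preset, stats in report["mossbauer"].items():
        lines.append(f"- {preset}: Fe2+ share "
                     f"{stats['fe2_share_percent_mean']:.2f}%; siderite "
                     f"{stats['siderite_percent_mean']:.2f}%")
    g = report["genome"]
    lines.append("")
    lines.append(f"- multihemes: {g['multihemes_strain_a']} (A) / "
                 f"{g['multihemes_strain_b']} (B); unique to B: "
                 f"{', '.join(g['unique_to_b']) or 'none'}")
    lines.append(f"- co-regulated operons recovered: "
                 f"{g['planted_coo_operons_recovered']} of 2")
    return "\n".join(lines) + "\n"


if __name__ == "__main__":  # pragma: no cover
    cli()
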