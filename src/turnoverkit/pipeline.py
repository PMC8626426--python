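"""End-to-end orchestration: ingest -> train -> fit -> simulate -> aggregate.

A :class:`FitRun` holds everything one tissue analysis produces: trained
coefficients, per-peptidoform fits with bootstrap half-life samples, protein
aggregates, and QC (filter attrition, messy peptides, exogenous suspects).
``write_run`` exports the plot-ready TSV/JSON artifacts; ``compare_runs``
and ``validate_missed_cleavage`` consume runs directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparison as cmp
from .fitting import (
    PeptideFit,
    TissueTrainingResult,
    TrainingConfig,
    fit_peptide_rate,
    train_tissue,
)
from .io import PeptideSeries, filter_series, remap_proteins, write_long_table
from .model import (
    TissueCoefficients,
    curve_table,
    exogenous_suspect,
    missed_cleavage_fractions,
)
from .uncertainty import (
    ProteinResult,
    SimulatedHalfLives,
    aggregate_protein,
    peptide_rng,
    simulate_peptide,
)

__all__ = [
    "FitRun",
    "run_pipeline",
    "write_run",
    "compare_runs",
    "validate_missed_cleavage",
    "histogram_table",
]

EXOGENOUS_TOL = 0.05
EXOGENOUS_MIN_FRACTION = 0.5


@dataclass
class FitRun:
    """All results of one tissue analysis."""

    tissue: str
    seed: int
    coefficients: TissueCoefficients
    training: TissueTrainingResult | None
    series: list[PeptideSeries]
    fits: list[PeptideFit]
    simulations: list[SimulatedHalfLives]
    proteins: list[ProteinResult]
    qc: dict = field(default_factory=dict)

    def fit_by_sequence(self, full_sequence: str) -> PeptideFit:
        for f in self.fits:
            if f.series.full_sequence == full_sequence:
                return f
        raise KeyError(full_sequence)

    def protein_by_id(self, protein_id: str) -> ProteinResult:
        for p in self.proteins:
            if p.protein_id == protein_id:
                return p
        raise KeyError(protein_id)

    def protein_series(self, protein_id: str) -> list[PeptideSeries]:
        return [
            f.series
            for f in self.fits
            if f.series.protein_id == protein_id and not f.series.missed_cleavage
        ]


def run_pipeline(
    series: list[PeptideSeries],
    database: dict[str, str] | None = None,
    tissue: str = "tissue",
    seed: int = 0,
    n_sims: int = 200,
    config: TrainingConfig | None = None,
    min_total: int = 6,
    min_single_timepoint: int = 3,
) -> FitRun:
    """Run the full half-life analysis for one tissue.

    Steps: validity filtering, optional protein remapping against the
    database (undoing parsimony), coefficient training on single-lysine
    peptides, per-peptidoform rate fits, 200 bootstrap simulations per
    peptide, and protein aggregation (shared-peptide groups aggregate
    separately).  Deterministic for a fixed seed.
    """
    config = config or TrainingConfig()
    n_input = len(series)
    kept, discarded = filter_series(series, min_total, min_single_timepoint)
    if not kept:
        raise ValueError("no peptide series survive the validity filters")
    remap_stats: dict[str, int] = {}
    if database:
        kept, remap_stats = remap_proteins(kept, database)

    training_pool = [s for s in kept if not s.missed_cleavage]
    training = train_tissue(training_pool, config)
    coeffs = training.coefficients

    fits = [fit_peptide_rate(s, coeffs) for s in kept]
    sims = [
        simulate_peptide(
            f.series, f, coeffs, n_sims=n_sims,
            rng=peptide_rng(seed, f.series.full_sequence),
        )
        for f in fits
    ]

    by_protein: dict[str, list[SimulatedHalfLives]] = {}
    for f, sim in zip(fits, sims):
        if f.series.missed_cleavage:
            continue  # two-lysine peptides validate the model, not proteins
        by_protein.setdefault(f.series.protein_id, []).append(sim)
    proteins = [
        aggregate_protein(pid, group) for pid, group in sorted(by_protein.items())
    ]

    suspects = []
    for f in fits:
        t, r = f.series.valid_points()
        if exogenous_suspect(t, r, coeffs, EXOGENOUS_TOL, EXOGENOUS_MIN_FRACTION):
            suspects.append(f.series.full_sequence)
    qc = {
        "n_series_input": n_input,
        "n_series_quantified": len(kept),
        "n_discarded_too_few_total": sum(
            1 for _, why in discarded if why == "too-few-total"
        ),
        "n_discarded_no_anchor_timepoint": sum(
            1 for _, why in discarded if why == "no-anchor-timepoint"
        ),
        "remap": remap_stats,
        "exogenous_suspects": sorted(suspects),
        "messy_sequences": sorted(training.messy_sequences),
    }
    return FitRun(
        tissue=tissue,
        seed=seed,
        coefficients=coeffs,
        training=training,
        series=kept,
        fits=fits,
        simulations=sims,
        proteins=proteins,
        qc=qc,
    )


def peptides_table(run: FitRun) -> pd.DataFrame:
    rows = []
    for f, sim in zip(run.fits, run.simulations):
        rows.append(
            {
                "full_sequence": f.series.full_sequence,
                "sequence": f.series.base_sequence,
                "protein_id": f.series.protein_id,
                "k_bi_per_day": f.k_bi,
                "half_life_d": f.half_life,
                "mse": f.mse,
                "n_valid": f.n_valid,
                "ci_low_d": sim.ci_low,
                "ci_high_d": sim.ci_high,
                "missed_cleavage": f.series.missed_cleavage,
                "flags": ";".join(f.flags),
            }
        )
    return pd.DataFrame(rows)


def proteins_table(run: FitRun) -> pd.DataFrame:
    rows = []
    for p in run.proteins:
        rows.append(
            {
                "protein_id": p.protein_id,
                "half_life_d": p.half_life,
                "ci_low_d": p.ci_low,
                "ci_high_d": p.ci_high,
                "n_peptides": p.n_peptides,
                "relative_ci": p.relative_ci,
            }
        )
    return pd.DataFrame(rows)


def histogram_table(
    half_lives, n_bins: int = 40, lo: float = 0.1, hi: float = 1000.0
) -> pd.DataFrame:
    """Log-spaced half-life histogram (counts per bin), plot-ready."""
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    counts, _ = np.histogram(np.asarray(half_lives, dtype=float), bins=edges)
    return pd.DataFrame(
        {"bin_low_d": edges[:-1], "bin_high_d": edges[1:], "count": counts}
    )


def write_run(run: FitRun, outdir: str | Path) -> dict[str, Path]:
    """Export all artifacts of a fitted run into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "coefficients": outdir / "coefficients.json",
        "peptides": outdir / "peptides.tsv",
        "proteins": outdir / "proteins.tsv",
        "histogram": outdir / "histogram.tsv",
        "curves": outdir / "curves.tsv",
        "observations": outdir / "observations.tsv",
        "qc": outdir / "qc.json",
    }
    coeff_doc = {
        "tissue": run.tissue,
        "seed": run.seed,
        "k_st": run.coefficients.k_st,
        "k_bt": run.coefficients.k_bt,
        "k_a0": run.coefficients.k_a0,
    }
    if run.training is not None:
        coeff_doc.update(
            final_mse=run.training.final_mse,
            rounds=run.training.diagnostics["rounds"],
            grid_sweeps=run.training.diagnostics["grid_sweeps"],
        )
    paths["coefficients"].write_text(json.dumps(coeff_doc, indent=2, sort_keys=True))
    peptides_table(run).to_csv(paths["peptides"], sep="\t", index=False)
    proteins_table(run).to_csv(paths["proteins"], sep="\t", index=False)
    histogram_table([p.half_life for p in run.proteins]).to_csv(
        paths["histogram"], sep="\t", index=False
    )
    t_max = max(
        (o.timepoint for s in run.series for o in s.observations), default=60.0
    )
    ks = sorted({f.k_bi for f in run.fits})
    sample = ks[:: max(1, len(ks) // 20)][:20]  # a representative curve family
    curve_table(run.coefficients, sample, t_max).to_csv(
        paths["curves"], sep="\t", index=False
    )
    write_long_table(run.series, paths["observations"])
    paths["qc"].write_text(json.dumps(run.qc, indent=2, sort_keys=True))
    return paths


def load_run(rundir: str | Path) -> FitRun:
    """Reload a written run directory into a FitRun.

    Reconstructs what the comparison and validation commands need:
    coefficients, observation series, per-peptide rates and protein
    half-lives.  Bootstrap simulation values are not persisted and come
    back empty.
    """
    from .io import read_quantified_peptides

    rundir = Path(rundir)
    doc = json.loads((rundir / "coefficients.json").read_text())
    coeffs = TissueCoefficients(doc["k_st"], doc["k_bt"], doc["k_a0"])
    series = read_quantified_peptides(rundir / "observations.tsv", dialect="long")
    by_seq = {s.full_sequence: s for s in series}
    pep = pd.read_csv(rundir / "peptides.tsv", sep="\t")
    fits = []
    for _, row in pep.iterrows():
        s = by_seq.get(str(row["full_sequence"]))
        if s is None:
            continue
        fits.append(
            PeptideFit(
                series=s,
                k_bi=float(row["k_bi_per_day"]),
                half_life=float(row["half_life_d"]),
                mse=float(row["mse"]),
                n_valid=int(row["n_valid"]),
                residuals=np.empty(0),
                flags=tuple(str(row.get("flags", "")).split(";"))
                if str(row.get("flags", "")) not in ("", "nan")
                else (),
            )
        )
    prot = pd.read_csv(rundir / "proteins.tsv", sep="\t")
    proteins = [
        ProteinResult(
            protein_id=str(row["protein_id"]),
            half_life=float(row["half_life_d"]),
            ci_low=float(row["ci_low_d"]),
            ci_high=float(row["ci_high_d"]),
            n_peptides=int(row["n_peptides"]),
            pooled_simulations=np.empty(0),
        )
        for _, row in prot.iterrows()
    ]
    qc = json.loads((rundir / "qc.json").read_text()) if (rundir / "qc.json").exists() else {}
    return FitRun(
        tissue=str(doc.get("tissue", rundir.name)),
        seed=int(doc.get("seed", 0)),
        coefficients=coeffs,
        training=None,
        series=series,
        fits=fits,
        simulations=[],
        proteins=proteins,
        qc=qc,
    )


def compare_runs(
    run_a: FitRun, run_b: FitRun, welch: bool = True
) -> tuple[list[cmp.ComparisonResult], dict]:
    """Protein comparisons for every protein shared between two runs.

    Also returns overlap counts (proteins per run and shared) for
    Venn-style reporting.
    """
    ids_a = {p.protein_id for p in run_a.proteins}
    ids_b = {p.protein_id for p in run_b.proteins}
    shared = sorted(ids_a & ids_b)
    results = []
    for pid in shared:
        pa = run_a.protein_by_id(pid)
        pb = run_b.protein_by_id(pid)
        try:
            results.append(
                cmp.compare_protein(
                    pid,
                    run_a.tissue, pa.half_life, run_a.protein_series(pid),
                    run_a.coefficients,
                    run_b.tissue, pb.half_life, run_b.protein_series(pid),
                    run_b.coefficients,
                    welch=welch,
                )
            )
        except cmp.NormalizationError:
            continue
    overlap = {
        "n_proteins_a": len(ids_a),
        "n_proteins_b": len(ids_b),
        "n_shared": len(shared),
    }
    return results, overlap


def proteoform_comparisons(runs: list[FitRun], welch: bool = True):
    """Modified-vs-unmodified peptidoform comparisons within each run."""
    entries = []
    coeffs_by_tissue = {}
    for run in runs:
        coeffs_by_tissue[run.tissue] = run.coefficients
        for f in run.fits:
            entries.append(
                {"tissue": run.tissue, "series": f.series, "half_life": f.half_life}
            )
    return cmp.compare_proteoforms(entries, coeffs_by_tissue, welch=welch)


def comparisons_table(results: list[cmp.ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "identifier": r.identifier,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "half_life_a_d": r.half_life_a,
                "half_life_b_d": r.half_life_b,
                "log2fc": r.log2_fold_change,
                "p_value": r.p_value,
                "neg_log10_p": r.neg_log10_p,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "significant": r.significant,
                "omitted_reason": r.omitted_reason or "",
            }
        )
    return pd.DataFrame(rows)


def validate_missed_cleavage(run: FitRun) -> tuple[pd.DataFrame, float]:
    """Expected-vs-observed label-combination fractions of missed-cleavage
    peptides, with the pooled R^2 across all observations.

    For each two-lysine peptide with three-way intensities, the model
    predicts (p00, p08, p88) at that peptide's fitted rate and timepoint;
    observed fractions come from the three intensity channels.
    """
    rows = []
    for f in run.fits:
        if not f.series.missed_cleavage:
            continue
        for o in f.series.observations:
            if o.intensity_00 is None or o.intensity_08 is None or o.intensity_88 is None:
                continue
            total = o.intensity_00 + o.intensity_08 + o.intensity_88
            if total <= 0:
                continue
            pred = missed_cleavage_fractions(run.coefficients, f.k_bi, o.timepoint)
            for channel, obs, exp in (
                ("Lys0Lys0", o.intensity_00 / total, pred.p00),
                ("Lys0Lys8", o.intensity_08 / total, pred.p08),
                ("Lys8Lys8", o.intensity_88 / total, pred.p88),
            ):
                rows.append(
                    {
                        "full_sequence": f.series.full_sequence,
                        "timepoint_d": o.timepoint,
                        "half_life_d": f.half_life,
                        "channel": channel,
                        "observed_fraction": obs,
                        "expected_fraction": exp,
                    }
                )
    table = pd.DataFrame(rows)
    if table.empty:
        return table, float("nan")
    obs = table["observed_fraction"].to_numpy()
    exp = table["expected_fraction"].to_numpy()
    ss_res = float(((obs - exp) ** 2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return table, r2
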