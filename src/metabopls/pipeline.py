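"""End-to-end orchestration: simulate / bucket / analyze / validate / enrich.

Every stage writes plain delimited text (or JSON) with the governing
parameters recorded, and a machine-readable run manifest accompanies
each full run.  A single global seed drives simulation, cross-validation
fold assignment and hold-out draws; per-stage seeds are derived from it
deterministically, so identical configurations produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotate import (
    assign_bins,
    load_shift_library,
    metabolite_fold_change,
    select_bins,
)
from .bucketing import (
    PAPER_EXCLUSIONS,
    BucketGrid,
    BucketTable,
    build_bucket_table,
    normalize_constant_sum,
    read_manifest,
    read_spectrum,
)
from .enrich import fisher_enrichment, read_gmt
from .opls import backscaled_coefficients, fit_oplsda
from .simulate import SimConfig, simulate_cohort, write_cohort
from .stats import attach_qvalues, student_t_per_bin
from .validate import holdout_classification

__all__ = ["RunConfig", "run_simulate", "run_bucket", "run_analyze", "run_all"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    spectra_dir: str | None = None
    manifest: str | None = None
    bucket_table: str | None = None
    shift_library: str | None = None
    gmt: str | None = None
    universe: str | None = None
    out_dir: str = "metabopls_out"

    width_ppm: float = 0.01
    range_ppm: tuple[float, float] = (0.0, 10.0)
    exclusions: list[tuple[float, float]] = field(
        default_factory=lambda: list(PAPER_EXCLUSIONS)
    )

    n_orth: int = 1
    cv_folds: int = 7
    q_cut: float = 0.2
    vip_cut: float = 1.5
    test_per_class: int = 3
    repeats: int = 4
    cutoff: float = 1.5
    treated_label: str = "treated"
    control_label: str = "control"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "range_ppm" in raw:
            raw["range_ppm"] = tuple(raw["range_ppm"])
        if "exclusions" in raw:
            raw["exclusions"] = [tuple(e) for e in raw["exclusions"]]
        return cls(**raw)

    def derived_seeds(self) -> dict[str, int]:
        rng = np.random.default_rng(self.seed)
        draws = rng.integers(0, 2**31, size=3)
        return {
            "simulate": int(self.seed),
            "cv_folds": int(draws[0]),
            "holdout": int(draws[1]),
        }

    def grid(self) -> BucketGrid:
        return BucketGrid(
            width_ppm=self.width_ppm,
            range_ppm=tuple(self.range_ppm),
            exclusions=tuple(tuple(e) for e in self.exclusions),
        )


def run_simulate(sim_config: SimConfig, out_dir) -> None:
    """Simulate a cohort and write spectra + manifest + ground truth."""
    spectra, truth = simulate_cohort(sim_config)
    write_cohort(spectra, truth, out_dir)


def load_spectra(spectra_dir, manifest_path) -> list:
    groups = read_manifest(manifest_path)
    spectra = []
    for sid, group in groups.items():
        path = Path(spectra_dir) / f"{sid}.tsv"
        spectra.append(read_spectrum(path, sample_id=sid, group=group))
    return spectra


def run_bucket(config: RunConfig) -> BucketTable:
    """Bucket input spectra (or load a precomputed table) and normalize."""
    if config.bucket_table:
        table = BucketTable.from_tsv(config.bucket_table)
    else:
        if not (config.spectra_dir and config.manifest):
            raise ValueError("need either bucket_table or spectra_dir + manifest")
        spectra = load_spectra(config.spectra_dir, config.manifest)
        table = build_bucket_table(spectra, config.grid())
    if not table.normalized:
        table = normalize_constant_sum(table)
    return table


def _write_bin_stats(path, stats, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# q_cut={config.q_cut} vip_cut={config.vip_cut} seed={config.seed}\n"
        )
        fh.write("ppm\tdirection\tfold_change\tt_stat\tp_value\tq_value\tvip\tselected\n")
        for s in stats:
            fh.write(
                f"{s.bin_center_ppm:.3f}\t{s.direction}\t{s.fold_change:.6g}\t"
                f"{s.t_stat:.6g}\t{s.p_value:.6g}\t{s.q_value:.6g}\t"
                f"{s.vip:.6g}\t{s.selected}\n"
            )


def run_analyze(config: RunConfig) -> dict:
    """Full analysis: bucket, test, model, validate, annotate, enrich.

    Returns the result bundle as a dict and writes every declared output
    under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.derived_seeds()

    table = run_bucket(config)
    table.to_tsv(
        out / "bucket_table.tsv",
        header_comment=(
            f"width={config.width_ppm} range={config.range_ppm} "
            f"exclusions={config.exclusions} seed={config.seed}"
        ),
    )

    stats = student_t_per_bin(table, config.treated_label, config.control_label)
    attach_qvalues(stats)

    model = fit_oplsda(
        table.matrix,
        np.asarray(table.groups),
        n_orth=config.n_orth,
        cv_folds=config.cv_folds,
        seed=seeds["cv_folds"],
        treated_label=config.treated_label,
        control_label=config.control_label,
    )
    # VIP is defined on the scaler-retained columns; map back to all bins
    vip_full = np.zeros(table.n_bins)
    vip_full[model.scaler_.retained_] = model.vip_
    for s, v in zip(stats, vip_full):
        s.vip = float(v)

    selected = select_bins(stats, q_cut=config.q_cut, vip_cut=config.vip_cut)
    _write_bin_stats(out / "bin_stats.tsv", stats, config)

    library = load_shift_library(config.shift_library)
    assignment = assign_bins(selected, library)
    metabolites = metabolite_fold_change(
        table, assignment, library, config.treated_label, config.control_label
    )
    with open(out / "metabolites.tsv", "w") as fh:
        fh.write(f"# q_cut={config.q_cut} vip_cut={config.vip_cut} seed={config.seed}\n")
        fh.write("metabolite\tkegg_id\tdirection\tavg_fold_change\tn_bins\tambiguous\n")
        for m in metabolites:
            fh.write(
                f"{m.metabolite}\t{m.kegg_id}\t{m.direction}\t"
                f"{m.avg_fold_change:.4g}\t{m.n_bins}\t{m.ambiguous}\n"
            )

    ppm, back, vips, color = backscaled_coefficients(model, table.bin_centers_ppm)
    with open(out / "backscaled_coefficients.tsv", "w") as fh:
        fh.write(f"# n_orth={config.n_orth} seed={config.seed}\n")
        fh.write("ppm\tback_coef\tvip\tcolor_value\n")
        for row in zip(ppm, back, vips, color):
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")

    summary = {
        "r2x": model.r2x_,
        "r2y": model.r2y_,
        "q2": model.q2_,
        "n_orth": config.n_orth,
        "cv_folds": config.cv_folds,
        "seed": config.seed,
    }
    (out / "model_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    report = holdout_classification(
        table,
        test_per_class=config.test_per_class,
        repeats=config.repeats,
        cutoff=config.cutoff,
        seed=seeds["holdout"],
        n_orth=config.n_orth,
        treated_label=config.treated_label,
        control_label=config.control_label,
    )
    (out / "cv_report.json").write_text(json.dumps(report.summary(), indent=2) + "\n")

    enrichment = None
    if config.gmt and config.universe:
        pathways = read_gmt(config.gmt)
        with open(config.universe) as fh:
            universe = {l.strip() for l in fh if l.strip() and not l.startswith("#")}
        query = {m.kegg_id for m in metabolites}
        enrichment = fisher_enrichment(query & universe, pathways, universe)
        with open(out / "enrichment.tsv", "w") as fh:
            fh.write(f"# universe={config.universe} seed={config.seed}\n")
            fh.write("pathway\tp_value\thits\tpathway_size\tratio\tbh_p\n")
            for r in enrichment:
                fh.write(
                    f"{r.pathway}\t{r.p_value:.3g}\t{r.hits}\t{r.pathway_size}\t"
                    f"{r.ratio:.3f}\t{r.bh_p:.3g}\n"
                )

    manifest = {
        "package_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "derived_seeds": seeds,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return {
        "table": table,
        "stats": stats,
        "model": model,
        "selected": selected,
        "metabolites": metabolites,
        "cv_report": report,
        "enrichment": enrichment,
        "summary": summary,
    }


def run_all(config: RunConfig, sim_config: SimConfig | None = None) -> dict:
    """Simulate (optionally) and run the whole analysis."""
    if sim_config is not None:
        cohort_dir = Path(config.out_dir) / "cohort"
        run_simulate(sim_config, cohort_dir)
        config = dataclasses.replace(
            config, spectra_dir=str(cohort_dir), manifest=str(cohort_dir / "manifest.tsv")
        )
    return run_analyze(config)
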