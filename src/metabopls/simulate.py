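"""Synthetic labeled 1H-NMR cohort generator.

Emulates the study design the pipeline was built for — a treated group of
12 rats vs a control group of 11, with roughly fifteen brain metabolites
carrying peaks between 0.6 and 8.3 ppm and multiplicative treatment
effects of magnitude 0.8–1.2 — so that every downstream stage (bucketing,
univariate testing, OPLS-DA, validation, annotation) can be exercised
against a known ground truth.

Peaks are Lorentzian (the natural NMR lineshape); noise is additive
i.i.d. Gaussian per grid point; an optional smooth polynomial baseline is
off by default.  FID-domain artifacts (phase errors, water suppression,
spinning sidebands) are not simulated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .bucketing import Spectrum

__all__ = [
    "Peak",
    "MetaboliteTemplate",
    "SimConfig",
    "GroundTruth",
    "load_default_templates",
    "default_amplitudes",
    "default_fold_changes",
    "render_spectrum",
    "simulate_cohort",
    "write_cohort",
]

#: Default planted multiplicative treatment effects (treated / control),
#: matching the magnitudes of metabolite-level fold changes observed in
#: cortex in the study this generator emulates.  Metabolites absent from
#: this map are unaffected (true fold change 1).
DEFAULT_FOLD_CHANGES: dict[str, float] = {
    "Scyllo-inositol": 1.15,
    "Acetate": 1.13,
    "L-Aspartate": 1.13,
    "NAA": 1.13,
    "L-Alanine": 1.12,
    "GABA": 1.09,
    "L-Serine": 1.07,
    "Succinate": 1.07,
    "L-Glutamine": 0.92,
    "Myo-inositol": 0.92,
    "Phosphorylcholine": 0.90,
    "Taurine": 0.88,
    "Citrate": 0.84,
}

#: Base (control-group) amplitudes, arbitrary concentration units chosen
#: to reflect typical relative abundances in brain tissue extracts.
DEFAULT_AMPLITUDES: dict[str, float] = {
    "Lactate": 1.5,
    "NAA": 3.0,
    "Creatine": 2.5,
    "Acetate": 0.5,
    "GABA": 1.0,
    "Phosphorylcholine": 1.0,
    "Choline": 0.6,
    "L-Valine": 0.3,
    "L-Alanine": 0.8,
    "L-Glutamate": 3.0,
    "L-Glutamine": 1.5,
    "L-Aspartate": 1.0,
    "Myo-inositol": 2.0,
    "Taurine": 2.5,
    "Succinate": 0.5,
    "Scyllo-inositol": 0.4,
    "L-Serine": 0.8,
    "Citrate": 0.6,
}

#: Default per-grid-point noise standard deviation.  Chosen so that a
#: bucket carrying the main peak of a unit-amplitude metabolite with a 10%
#: fold change shows a between-group difference of about three bucket-level
#: noise standard deviations (bucket noise sd = noise_sd * sqrt(points per
#: bucket)); see docs/methods.md for the derivation.
DEFAULT_NOISE_SD = 15.0


@dataclass(frozen=True)
class Peak:
    center_ppm: float
    relative_intensity: float
    halfwidth_ppm: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 <= self.center_ppm <= 10.0:
            raise ValueError(f"peak center {self.center_ppm} outside 0-10 ppm")
        if not (np.isfinite(self.relative_intensity) and self.relative_intensity > 0):
            raise ValueError("relative_intensity must be finite and positive")
        if self.halfwidth_ppm <= 0:
            raise ValueError("halfwidth_ppm must be positive")


@dataclass(frozen=True)
class MetaboliteTemplate:
    name: str
    kegg_id: str
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"metabolite {self.name!r} has no peaks")


def load_default_templates(path=None) -> list[MetaboliteTemplate]:
    """Load peak templates from the packaged (or a user-supplied) TSV."""
    if path is None:
        source = resources.files("metabopls.data").joinpath("peak_templates.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    rows: dict[str, tuple[str, list[Peak]]] = {}
    reader = csv.reader(
        (l for l in text.splitlines() if l.strip() and not l.startswith("#")),
        delimiter="\t",
    )
    header = next(reader)
    if header[0] != "metabolite":
        raise ValueError("peak template file must have a 'metabolite' header column")
    for row in reader:
        name, kegg, center, rel, hw = row[:5]
        rows.setdefault(name, (kegg, []))[1].append(
            Peak(float(center), float(rel), float(hw))
        )
    return [
        MetaboliteTemplate(name=name, kegg_id=kegg, peaks=tuple(peaks))
        for name, (kegg, peaks) in rows.items()
    ]


def default_amplitudes() -> dict[str, float]:
    return dict(DEFAULT_AMPLITUDES)


def default_fold_changes() -> dict[str, float]:
    return dict(DEFAULT_FOLD_CHANGES)


@dataclass
class SimConfig:
    """Full description of a simulated cohort.

    ``planted_fold_changes`` multiply the treated group's amplitudes;
    metabolites not listed keep fold change 1.
    """

    n_treated: int = 12
    n_control: int = 11
    templates: list[MetaboliteTemplate] = field(default_factory=load_default_templates)
    planted_fold_changes: dict[str, float] = field(default_factory=default_fold_changes)
    base_amplitudes: dict[str, float] = field(default_factory=default_amplitudes)
    noise_sd: float = DEFAULT_NOISE_SD
    grid: tuple[float, float, float] = (0.0, 10.0, 0.0005)
    baseline_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treated < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 samples")
        lo, hi, step = self.grid
        if step <= 0 or not lo < hi:
            raise ValueError("grid must satisfy step > 0 and min < max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.baseline_amplitude < 0:
            raise ValueError("baseline_amplitude must be non-negative")
        names = {t.name for t in self.templates}
        for key, fc in self.planted_fold_changes.items():
            if key not in names:
                raise ValueError(f"planted fold change for unknown metabolite {key!r}")
            if not fc > 0:
                raise ValueError(f"fold change for {key!r} must be strictly positive")
        for key, amp in self.base_amplitudes.items():
            if key not in names:
                raise ValueError(f"amplitude for unknown metabolite {key!r}")
            if not amp > 0:
                raise ValueError(f"amplitude for {key!r} must be strictly positive")

    def grid_ppm(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(np.floor((hi - lo) / step + 1e-9)) + 1
        return lo + step * np.arange(n)


@dataclass
class GroundTruth:
    """Planted effects and labels of a simulated cohort."""

    affected_metabolites: set[str]
    fold_changes: dict[str, float]
    groups: dict[str, str]  # sample_id -> "treated" / "control"


def _lorentzian(ppm: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    # unit-area Lorentzian
    return (halfwidth / np.pi) / ((ppm - center) ** 2 + halfwidth**2)


def render_spectrum(
    templates: list[MetaboliteTemplate],
    amplitudes: dict[str, float],
    grid_ppm: np.ndarray,
    baseline_amplitude: float = 0.0,
) -> np.ndarray:
    """Noise-free intensities: sum of amplitude-weighted Lorentzian peaks.

    ``amplitudes`` must only reference metabolites present in ``templates``;
    a missing template is a configuration error.  The optional baseline is a
    smooth non-negative quadratic bump spanning the grid.
    """
    by_name = {t.name: t for t in templates}
    unknown = set(amplitudes) - set(by_name)
    if unknown:
        raise ValueError(f"amplitudes reference unknown metabolites: {sorted(unknown)}")
    intensity = np.zeros_like(grid_ppm, dtype=float)
    for name, amp in amplitudes.items():
        for peak in by_name[name].peaks:
            intensity += (
                amp
                * peak.relative_intensity
                * _lorentzian(grid_ppm, peak.center_ppm, peak.halfwidth_ppm)
            )
    if baseline_amplitude > 0:
        x = (grid_ppm - grid_ppm[0]) / (grid_ppm[-1] - grid_ppm[0])
        intensity += baseline_amplitude * 4.0 * x * (1.0 - x)
    return intensity


def snr_calibrated_config(
    target_snr: float = 3.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    fold_changes: dict[str, float] | None = None,
    null_reference_effect: float = 0.1,
    bucket_width_ppm: float = 0.01,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """Build a cohort whose affected buckets sit at a prescribed SNR.

    For each affected metabolite the base amplitude is solved so that its
    strongest bucket's between-group mean difference equals ``target_snr``
    bucket-level noise standard deviations (bucket noise sd =
    ``noise_sd * sqrt(points per bucket)``).  Unaffected metabolites get
    the amplitude an affected metabolite with fold change
    ``1 + null_reference_effect`` would receive, keeping the concentration
    scale uniform.  Amplitudes depend only on the noise-free lineshapes,
    never on any simulated draw.
    """
    base = SimConfig(seed=seed, noise_sd=noise_sd, **overrides)
    if fold_changes is None:
        fold_changes = dict(base.planted_fold_changes)
    lo, hi, step = base.grid
    ppm = base.grid_ppm()
    points_per_bucket = bucket_width_ppm / step
    bucket_noise_sd = noise_sd * np.sqrt(points_per_bucket)
    amplitudes: dict[str, float] = {}
    for tpl in base.templates:
        unit = render_spectrum([tpl], {tpl.name: 1.0}, ppm)
        # strongest bucket of the unit-amplitude lineshape
        n_buckets = int(np.floor((hi - lo) / bucket_width_ppm + 1e-9))
        idx = np.minimum(
            np.floor((ppm - lo) / bucket_width_ppm).astype(int), n_buckets - 1
        )
        best = float(np.bincount(idx, weights=unit, minlength=n_buckets).max())
        fc = fold_changes.get(tpl.name, 1.0)
        effect = abs(fc - 1.0) if fc != 1.0 else null_reference_effect
        amplitudes[tpl.name] = target_snr * bucket_noise_sd / (effect * best)
    return SimConfig(
        n_treated=base.n_treated,
        n_control=base.n_control,
        templates=base.templates,
        planted_fold_changes=fold_changes,
        base_amplitudes=amplitudes,
        noise_sd=noise_sd,
        grid=base.grid,
        baseline_amplitude=base.baseline_amplitude,
        seed=seed,
    )


def simulate_cohort(config: SimConfig) -> tuple[list[Spectrum], GroundTruth]:
    """Simulate one labeled cohort; identical config+seed is reproducible."""
    rng = np.random.default_rng(config.seed)
    ppm = config.grid_ppm()

    control_amp = dict(config.base_amplitudes)
    treated_amp = {
        name: amp * config.planted_fold_changes.get(name, 1.0)
        for name, amp in control_amp.items()
    }
    clean_control = render_spectrum(
        config.templates, control_amp, ppm, config.baseline_amplitude
    )
    clean_treated = render_spectrum(
        config.templates, treated_amp, ppm, config.baseline_amplitude
    )

    spectra: list[Spectrum] = []
    groups: dict[str, str] = {}
    for i in range(config.n_treated):
        sid = f"treated_{i + 1:02d}"
        noise = rng.normal(0.0, config.noise_sd, ppm.size) if config.noise_sd else 0.0
        spectra.append(Spectrum(sid, ppm, clean_treated + noise, group="treated"))
        groups[sid] = "treated"
    for i in range(config.n_control):
        sid = f"control_{i + 1:02d}"
        noise = rng.normal(0.0, config.noise_sd, ppm.size) if config.noise_sd else 0.0
        spectra.append(Spectrum(sid, ppm, clean_control + noise, group="control"))
        groups[sid] = "control"

    affected = {
        name
        for name, fc in config.planted_fold_changes.items()
        if fc != 1.0 and name in config.base_amplitudes
    }
    truth = GroundTruth(
        affected_metabolites=affected,
        fold_changes={
            name: config.planted_fold_changes.get(name, 1.0)
            for name in config.base_amplitudes
        },
        groups=groups,
    )
    return spectra, truth


def write_cohort(spectra: list[Spectrum], truth: GroundTruth, out_dir) -> None:
    """Write per-sample two-column files, a manifest and a truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for spec in spectra:
        with open(out / f"{spec.sample_id}.tsv", "w") as fh:
            fh.write("ppm\tintensity\n")
            for x, y in zip(spec.ppm, spec.intensity):
                fh.write(f"{x:.4f}\t{y:.10g}\n")
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, group in truth.groups.items():
            fh.write(f"{sid}\t{group}\n")
    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write("metabolite\ttrue_fold_change\taffected\n")
        for name, fc in sorted(truth.fold_changes.items()):
            fh.write(f"{name}\t{fc}\t{name in truth.affected_metabolites}\n")
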