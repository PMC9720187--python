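"""Synthetic multi-subject surface decoding datasets with known ground truth.

Each subject gets R runs of vertex-wise Gaussian noise on the
high-resolution sphere; at every trial's sampled volume a condition-specific
multivariate pattern is added inside a known geodesic patch.  Patterns are
drawn fresh per subject (fine-grained patterns are not assumed to align
across subjects — only decodability is shared), and no hemodynamic
convolution is applied: information is injected directly at the volume the
trial-extraction step reads.

Default sizes are deliberately small-sphere (high_div 16 -> 2,562 vertices,
low_div 4 -> 162) so a full pipeline run is quick; the full 128/40
resolution is available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import ParadigmEvent, RunSeries, write_paradigm, write_surface_series
from .sphere import GeodesicSphere, base_icosahedron, subdivide


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults give a quick 8-subject two-condition study."""

    high_div: int = 16
    low_div: int = 4
    n_subjects: int = 8
    n_runs: int = 3
    trials_per_condition_per_run: int = 10
    conditions: tuple = (1, 2)
    tr: float = 1.0
    timepoint: float = 7.0
    iti: float = 12.0              # onset-to-onset spacing, seconds
    patch_center: int = 0          # downsampled vertex index
    patch_radius: float = 0.3      # radians
    effect_size: float = 1.5       # pattern sd / noise sd
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.n_runs,
               self.trials_per_condition_per_run) < 1:
            raise ValueError("all counts must be positive")
        if len(self.conditions) < 2 or 0 in self.conditions:
            raise ValueError("need >= 2 non-baseline condition codes")
        if self.patch_radius <= 0:
            raise ValueError("patch_radius must be positive")

    @property
    def pattern_sd(self) -> float:
        # effect size is relative to the noise; with noiseless data the
        # amplitude itself is the effect size
        return self.effect_size * (self.noise_sd if self.noise_sd > 0 else 1.0)


@dataclass
class GroundTruth:
    """High-res vertices carrying information and the per-condition patterns."""

    patch_vertices: np.ndarray
    patterns: dict  # condition code -> pattern over patch vertices
    patch_center: int


@dataclass
class SubjectData:
    subject_id: str
    runs: list            # RunSeries per run
    paradigms: list       # list of ParadigmEvent lists
    ground_truth: GroundTruth


@dataclass
class Dataset:
    config: SimConfig
    high: GeodesicSphere = field(repr=False)
    low: GeodesicSphere = field(repr=False)
    subjects: list = field(default_factory=list)


def _patch_vertices(high: GeodesicSphere, low: GeodesicSphere,
                    config: SimConfig) -> np.ndarray:
    center = low.vertices[config.patch_center]
    cosd = np.clip(high.vertices @ center, -1.0, 1.0)
    return np.flatnonzero(np.arccos(cosd) <= config.patch_radius)


def simulate_subject(config: SimConfig, subject_seed: int,
                     high: GeodesicSphere = None, low: GeodesicSphere = None,
                     subject_id: str = "Sub01") -> SubjectData:
    """Generate one subject: paradigms, noisy run series, and ground truth."""
    ico = base_icosahedron()
    if high is None:
        high = subdivide(ico, config.high_div)
    if low is None:
        low = subdivide(ico, config.low_div)
    rng = np.random.default_rng(subject_seed)
    patch = _patch_vertices(high, low, config)
    patterns = {c: rng.normal(0.0, config.pattern_sd, size=len(patch))
                for c in config.conditions}

    n_trials = config.trials_per_condition_per_run * len(config.conditions)
    n_vol = int(np.ceil(((n_trials - 1) * config.iti + config.timepoint)
                        / config.tr)) + 3
    if int(np.round(((n_trials - 1) * config.iti + config.timepoint)
                    / config.tr)) >= n_vol:
        raise ValueError("trials overrun the simulated series length")

    runs, paradigms = [], []
    for r in range(config.n_runs):
        codes = np.repeat(config.conditions,
                          config.trials_per_condition_per_run)
        rng.shuffle(codes)
        events = [ParadigmEvent(onset=float(k * config.iti), code=int(c),
                                duration=2.0, weight=1.0)
                  for k, c in enumerate(codes)]
        data = rng.normal(0.0, config.noise_sd,
                          size=(n_vol, high.n_vertices)) if config.noise_sd > 0 \
            else np.zeros((n_vol, high.n_vertices))
        for e in events:
            idx = int(np.round((e.onset + config.timepoint) / config.tr))
            data[idx, patch] += patterns[e.code]
        runs.append(RunSeries(data=data, tr=config.tr,
                              run_id=f"{subject_id}/{r + 1:03d}"))
        paradigms.append(events)

    return SubjectData(subject_id=subject_id, runs=runs, paradigms=paradigms,
                       ground_truth=GroundTruth(patch_vertices=patch,
                                                patterns=patterns,
                                                patch_center=config.patch_center))


def simulate_dataset(config: SimConfig, prefix: str = "Sub") -> Dataset:
    """Generate the full multi-subject dataset deterministically from config.seed."""
    ico = base_icosahedron()
    high = subdivide(ico, config.high_div)
    low = subdivide(ico, config.low_div)
    seeds = (np.random.SeedSequence(config.seed)
             .generate_state(config.n_subjects) & 0x7FFFFFFF)
    subjects = [
        simulate_subject(config, int(seeds[s]), high=high, low=low,
                         subject_id=f"{prefix}{s + 1:02d}")
        for s in range(config.n_subjects)
    ]
    return Dataset(config=config, high=high, low=low, subjects=subjects)


def write_dataset(dataset: Dataset, out_dir, hemi: str = "lh",
                  force: bool = False) -> Path:
    """Write the dataset as a subjects directory tree.

    Layout: ``<out>/<SubjectID>/bold/<RRR>/f.fsaverage.<hemi>.nii.gz`` plus a
    ``paradigm.par`` per run folder, readable back by the dataset I/O layer.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    for subj in dataset.subjects:
        for r, (run, events) in enumerate(zip(subj.runs, subj.paradigms),
                                          start=1):
            run_dir = out / subj.subject_id / "bold" / f"{r:03d}"
            run_dir.mkdir(parents=True, exist_ok=True)
            write_surface_series(run, run_dir / f"f.fsaverage.{hemi}.nii.gz")
            write_paradigm(events, run_dir / "paradigm.par")
    return out


def scaled_config(config: SimConfig, **overrides) -> SimConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
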