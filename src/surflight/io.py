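"""Paradigm files, surface functional series, and trial extraction.

Paradigm files are 4-column whitespace text: onset (s), condition code
(0 = baseline), duration (s), weight.  Surface functional series are
surface-encoded NIfTI (vertices along the spatial axes, time along the 4th)
or GIFTI functional files, one hemisphere per file.  A trial's pattern is
the single volume nearest to onset + timepoint (round-half-to-even on the
volume index); no interpolation or HRF fitting is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ParadigmFormatError(ValueError):
    """A paradigm or delay file violates the documented format."""


@dataclass(frozen=True)
class ParadigmEvent:
    onset: float
    code: int
    duration: float
    weight: float


@dataclass
class RunSeries:
    """One run's vertex-wise time series for one hemisphere."""

    data: np.ndarray  # (timepoints, V_high)
    tr: float
    run_id: str

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialSet:
    """Per-trial vertex patterns with condition labels and run identifiers."""

    patterns: np.ndarray  # (trials, V_high)
    labels: np.ndarray    # condition codes
    runs: np.ndarray      # run identifier per trial
    timepoint: float      # seconds after onset at which patterns were sampled

    def __post_init__(self):
        if not (len(self.patterns) == len(self.labels) == len(self.runs)):
            raise ValueError("patterns, labels and runs must have equal length")

    @property
    def n_trials(self) -> int:
        return len(self.patterns)


def concat_trialsets(sets) -> TrialSet:
    """Stack per-run trial sets into one (order preserved)."""
    sets = list(sets)
    return TrialSet(
        patterns=np.vstack([s.patterns for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        runs=np.concatenate([s.runs for s in sets]),
        timepoint=sets[0].timepoint,
    )


# ---------------------------------------------------------------------------
# paradigm and delay files

def read_paradigm(path) -> list:
    """Parse a 4-column paradigm file into a list of events.

    Onsets must be non-negative and strictly increasing; errors name the
    offending line.
    """
    events = []
    prev_onset = -np.inf
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParadigmFormatError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                onset, code, duration, weight = (float(p) for p in parts)
            except ValueError:
                raise ParadigmFormatError(
                    f"{path}:{lineno}: non-numeric field in {parts!r}") from None
            if code != int(code) or code < 0:
                raise ParadigmFormatError(
                    f"{path}:{lineno}: condition code must be a non-negative "
                    f"integer, got {parts[1]}")
            if onset < 0:
                raise ParadigmFormatError(f"{path}:{lineno}: negative onset {onset}")
            if onset <= prev_onset:
                raise ParadigmFormatError(
                    f"{path}:{lineno}: onsets must be strictly increasing "
                    f"({onset} after {prev_onset})")
            prev_onset = onset
            events.append(ParadigmEvent(onset, int(code), duration, weight))
    return events


def write_paradigm(events, path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(f"{e.onset:g} {e.code} {e.duration:g} {e.weight:g}\n")


def read_delay_file(path) -> np.ndarray:
    """Read a slice-delay file: one fraction of TR per slice, in [-0.5, 0.5].

    Parsed and validated only; slice-timing correction itself belongs to the
    upstream preprocessing.
    """
    delays = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                d = float(line.split()[0])
            except ValueError:
                raise ParadigmFormatError(
                    f"{path}:{lineno}: non-numeric delay") from None
            if not -0.5 <= d <= 0.5:
                raise ParadigmFormatError(
                    f"{path}:{lineno}: delay {d} outside [-0.5, 0.5]")
            delays.append(d)
    return np.asarray(delays)


# ---------------------------------------------------------------------------
# surface functional series

def read_surface_series(path, expected_vertices: int = None, tr: float = 1.0,
                        run_id: str = "") -> RunSeries:
    """Read a surface functional file into a (timepoints, vertices) matrix.

    Accepts surface-encoded NIfTI (.nii/.nii.gz; the product of the three
    spatial dimensions is the vertex count) and GIFTI functional files
    (.func.gii/.gii; one data array per timepoint).
    """
    import nibabel as nib
    p = str(path)
    if p.endswith(".gii"):
        img = nib.load(p)
        data = np.stack([d.data for d in img.darrays]).astype(np.float64)
    else:
        img = nib.load(p)
        arr = np.asanyarray(img.dataobj)
        if arr.ndim == 4:
            nv = arr.shape[0] * arr.shape[1] * arr.shape[2]
            data = arr.reshape(nv, arr.shape[3]).T.astype(np.float64)
        elif arr.ndim == 2:
            data = arr.T.astype(np.float64)
        else:
            raise IOError(f"{path}: expected a 4D surface-encoded NIfTI, got "
                          f"{arr.ndim}D")
    if expected_vertices is not None and data.shape[1] != expected_vertices:
        raise ValueError(
            f"{path}: {data.shape[1]} vertices, template expects {expected_vertices}")
    return RunSeries(data=data, tr=tr, run_id=run_id or p)


def write_surface_series(series: RunSeries, path) -> None:
    """Write a run as a surface-encoded NIfTI (V, 1, 1, T) or GIFTI file."""
    import nibabel as nib
    p = str(path)
    if p.endswith(".gii"):
        darrays = [nib.gifti.GiftiDataArray(row.astype(np.float32),
                                            intent="NIFTI_INTENT_TIME_SERIES")
                   for row in series.data]
        nib.save(nib.gifti.GiftiImage(darrays=darrays), p)
    else:
        vol = series.data.T.reshape(series.n_vertices, 1, 1, series.n_timepoints)
        img = nib.Nifti1Image(vol.astype(np.float64), affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, series.tr))
        nib.save(img, p)


# ---------------------------------------------------------------------------
# trial extraction

def extract_trials(run: RunSeries, events, timepoint_s: float,
                   include_baseline: bool = False) -> TrialSet:
    """Sample one volume per event at ``timepoint_s`` seconds after onset.

    The volume index is round((onset + timepoint)/tr) with numpy's
    round-half-to-even.  Baseline events (code 0) are dropped unless
    ``include_baseline``.  Event order is preserved.
    """
    if timepoint_s < 0:
        raise ValueError(f"timepoint must be non-negative, got {timepoint_s}")
    rows, labels = [], []
    for e in events:
        if e.code == 0 and not include_baseline:
            continue
        idx = int(np.round((e.onset + timepoint_s) / run.tr))
        if idx >= run.n_timepoints:
            raise IndexError(
                f"event at onset {e.onset}s samples volume {idx}, but run "
                f"'{run.run_id}' has only {run.n_timepoints} volumes")
        rows.append(run.data[idx])
        labels.append(e.code)
    patterns = (np.vstack(rows) if rows
                else np.empty((0, run.n_vertices)))
    return TrialSet(
        patterns=patterns,
        labels=np.asarray(labels, dtype=np.int64),
        runs=np.asarray([run.run_id] * len(labels)),
        timepoint=float(timepoint_s),
    )
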