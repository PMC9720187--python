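"""End-to-end pipeline: template -> layout -> extract -> decode -> stats.

A pipeline run reads a subjects directory (one folder per subject with a
common prefix, run subfolders holding a surface series and a paradigm
file), decodes the configured contrast per subject, and performs group
cluster inference, writing all products plus a manifest recording
parameters and seeds.  Subjects are processed independently with a
deterministic reduction order, so results do not depend on the worker
count.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from .decode import subject_accuracy_map
from .group import ClusterPermutation
from .io import concat_trialsets, extract_trials, read_paradigm, read_surface_series
from .searchlight import GridSpec, build_layout, load_layout, save_layout
from .sphere import base_icosahedron, build_adjacency, nearest_assignment, subdivide


class ContrastParseError(ValueError):
    """A contrast string is empty, one-sided, or reuses a code."""


def parse_contrast(text: str) -> list:
    """Parse a contrast string into a list of superclasses (code sets).

    ``"1 vs 4"`` -> [{1}, {4}]; ``"2 3 vs 1 4"`` -> [{2, 3}, {1, 4}];
    ``"0 1 2 3 4"`` -> one class per code.  Chance downstream is
    1/len(superclasses).
    """
    text = text.strip().replace("vs.", "vs")
    if not text:
        raise ContrastParseError("empty contrast")
    sides = [s.strip() for s in text.split("vs")]
    groups = []
    for side in sides:
        if not side:
            raise ContrastParseError(f"empty side in contrast {text!r}")
        try:
            codes = [int(tok) for tok in side.split()]
        except ValueError:
            raise ContrastParseError(
                f"non-integer condition code in {side!r}") from None
        if len(sides) == 1:
            groups.extend(frozenset([c]) for c in codes)
        else:
            groups.append(frozenset(codes))
    seen = set()
    for g in groups:
        if seen & g:
            raise ContrastParseError(
                f"condition codes repeated across classes in {text!r}")
        seen |= g
    if len(groups) < 2:
        raise ContrastParseError(f"contrast {text!r} has fewer than 2 classes")
    return groups


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults mirror the method's defaults."""

    data_dir: str = "."
    out_dir: str = "out"
    subject_prefix: str = "Sub"
    hemi: str = "lh"
    high_div: int = 16
    low_div: int = 4
    cell_size: float = 1.0 / 35.0
    grid_size: int = 11
    tr: float = 1.0
    timepoint: float = 7.0
    contrast: str = "1 vs 2"
    classifier: str = "svm"
    vertexwise: float = 3.0
    fwe_alpha: float = 0.01
    n_perm: int = 2000
    perm_mode: str = "tmap"
    n_jobs: int = 1
    seed: int = 0


def discover_subjects(data_dir, prefix: str) -> list:
    """Subject folders under ``data_dir`` sharing ``prefix``, sorted by name."""
    root = Path(data_dir)
    return sorted(p for p in root.iterdir()
                  if p.is_dir() and p.name.startswith(prefix))


def _subject_trials(subj_dir: Path, hemi: str, tr: float, timepoint: float,
                    n_high: int):
    run_dirs = sorted((subj_dir / "bold").iterdir())
    sets = []
    for rd in run_dirs:
        series_files = sorted(rd.glob(f"*.{hemi}.nii*")) + \
            sorted(rd.glob(f"*.{hemi}.func.gii"))
        par_files = sorted(rd.glob("*.par"))
        if not series_files or not par_files:
            raise FileNotFoundError(
                f"{rd}: missing surface series or paradigm file")
        run = read_surface_series(series_files[0], expected_vertices=n_high,
                                  tr=tr, run_id=str(rd))
        events = read_paradigm(par_files[0])
        sets.append(extract_trials(run, events, timepoint))
    return concat_trialsets(sets)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig, layout_path=None) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Writes per-subject accuracy maps, the group t-map, the permutation null,
    the cluster table (TSV) and ``manifest.json`` under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = GridSpec(cell_size=config.cell_size, n1=config.grid_size)
    contrast = parse_contrast(config.contrast)

    subj_dirs = discover_subjects(config.data_dir, config.subject_prefix)
    if not subj_dirs:
        raise FileNotFoundError(
            f"no subject folders with prefix {config.subject_prefix!r} "
            f"under {config.data_dir}")

    ico = base_icosahedron()
    high = subdivide(ico, config.high_div)
    low = subdivide(ico, config.low_div)
    adjacency = build_adjacency(low)
    if layout_path is not None and Path(layout_path).exists():
        layout = load_layout(layout_path)
    else:
        mapping = nearest_assignment(high, low)
        layout = build_layout(high, low, mapping, adjacency, spec)
        cache = layout_path or out / f"{spec.stem}_{config.hemi}.npz"
        save_layout(layout, cache)

    def one_subject(sd: Path):
        trials = _subject_trials(sd, config.hemi, config.tr,
                                 config.timepoint, high.n_vertices)
        amap = subject_accuracy_map(trials, layout, contrast=contrast,
                                    classifier=config.classifier,
                                    subject_id=sd.name,
                                    random_state=config.seed)
        return amap

    maps = Parallel(n_jobs=config.n_jobs)(
        delayed(one_subject)(sd) for sd in subj_dirs)
    for amap in maps:
        np.save(out / f"accuracy_{amap.subject_id}_{config.hemi}.npy",
                amap.accuracy)

    infer = ClusterPermutation(adjacency, vertexwise=config.vertexwise,
                               fwe_alpha=config.fwe_alpha,
                               n_perm=config.n_perm, mode=config.perm_mode,
                               random_state=config.seed)
    infer.fit(maps, coords=layout.coords)
    np.save(out / f"tmap_{config.hemi}.npy", infer.tmap_.t)
    np.save(out / f"null_max_sizes_{config.hemi}.npy", infer.null_.max_sizes)
    infer.report_.to_csv(out / f"clusters_{config.hemi}.tsv", sep="\t",
                         index=False)

    from . import __version__ as version
    manifest = {
        "version": version,
        "config": asdict(config),
        "n_subjects": len(subj_dirs),
        "subjects": [sd.name for sd in subj_dirs],
        "chance": maps[0].chance,
        "n_clusters": len(infer.clusters_),
        "n_surviving": len(infer.surviving_),
        "null_threshold_size": infer.null_.threshold_size,
        "inputs": {sd.name: sorted(str(p.relative_to(sd)) + ":" + _digest(p)
                                   for p in sd.rglob("*") if p.is_file())
                   for sd in subj_dirs},
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
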