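"""Readers and writers: NIfTI volumes, stimulus timing text, YAML config.

Functional runs are 4D NIfTI files (one per run/state) sharing a spatial
grid and length T; the brain mask is a 3D 0/1 NIfTI on the same grid.
Stimulus timing is plain text in either of two dialects:

* indicator matrix — T rows by R whitespace-separated 0/1 columns, with an
  optional first line of non-numeric column labels;
* onset list — lines of ``label onset_seconds``, converted to indicators at
  TR resolution (onset floored to the containing TR bin, 0-based, time
  origin at acquisition start).

Statistical output is one 3D volume per (contrast, band) for F and p, a
small-integer multi-P label volume per contrast with a text legend, and a
tab-separated manifest listing every file with its contrast, band center
and degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .spectral import ConfigurationError, MultiRunSeries, StimulusSet
from .masks import DEFAULT_P_LEVELS, multi_p_mask

__all__ = [
    "load_runs",
    "load_stimuli",
    "write_runs",
    "write_stat_maps",
    "load_config",
]


class InputError(ValueError):
    """Raised for malformed or inconsistent input files."""


def _load_img(path) -> tuple[np.ndarray, np.ndarray, nib.Nifti1Image]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine, img


def load_runs(
    paths, mask_path, run_labels=None, tr: float | None = None
) -> MultiRunSeries:
    """Read S functional runs and a brain mask into a MultiRunSeries.

    All runs must share the 4D shape; the mask must match their spatial
    grid.  TR is read from the first image header; an explicit ``tr``
    overrides it (with a warning if they disagree).
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise InputError("need at least one functional run")
    vols, affine = [], None
    shape = None
    for p in paths:
        data, aff, img = _load_img(p)
        if data.ndim != 4:
            raise InputError(f"{p}: expected a 4D volume, got shape {data.shape}")
        if shape is None:
            shape, affine = data.shape, aff
            header_tr = float(img.header.get_zooms()[3]) if len(
                img.header.get_zooms()) > 3 else 0.0
        elif data.shape != shape:
            raise InputError(
                f"{p}: shape {data.shape} differs from first run {shape}"
            )
        vols.append(data)
    mask_data, _, _ = _load_img(mask_path)
    if mask_data.shape != shape[:3]:
        raise InputError(
            f"mask shape {mask_data.shape} does not match run grid {shape[:3]}"
        )
    mask = mask_data > 0.5
    if not mask.any():
        raise InputError("mask selects no voxels")
    if tr is None:
        tr = header_tr if header_tr > 0 else 2.0
    elif header_tr > 0 and not math.isclose(tr, header_tr, rel_tol=1e-6):
        warnings.warn(
            f"configured TR {tr} s overrides header TR {header_tr} s",
            stacklevel=2,
        )
    values = np.stack([v[mask] for v in vols], axis=1)  # (V, S, T)
    labels = tuple(run_labels) if run_labels else tuple(p.stem for p in paths)
    return MultiRunSeries(values, labels, shape[:3], mask, tr)


def load_stimuli(path, T: int, TR: float) -> StimulusSet:
    """Parse a stimulus timing file into a StimulusSet of length T."""
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise InputError(f"{path}: empty stimulus file")

    def numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    # onset-list dialect: every line is "label onset_seconds"
    if all(len(ln) == 2 and not numeric(ln[0]) and numeric(ln[1]) for ln in lines):
        labels = list(dict.fromkeys(ln[0] for ln in lines))
        ind = np.zeros((T, len(labels)))
        for label, onset in lines:
            t = float(onset)
            if t < 0 or t >= T * TR:
                raise InputError(
                    f"{path}: onset {t} s outside the acquisition [0, {T * TR}) s"
                )
            ind[int(t // TR), labels.index(label)] = 1.0
        return StimulusSet(ind, tuple(labels), TR)

    # indicator dialect, optional label header
    labels = None
    if not all(numeric(tok) for tok in lines[0]):
        labels, lines = tuple(lines[0]), lines[1:]
    try:
        ind = np.array([[float(tok) for tok in ln] for ln in lines])
    except ValueError as exc:
        raise InputError(f"{path}: unparseable indicator matrix") from exc
    if ind.ndim != 2 or len({len(ln) for ln in lines}) != 1:
        raise InputError(f"{path}: ragged indicator matrix")
    if not np.isin(ind, (0.0, 1.0)).all():
        raise InputError(f"{path}: indicator values must be 0 or 1")
    if ind.shape[0] != T:
        raise InputError(f"{path}: {ind.shape[0]} rows for T={T} timepoints")
    if labels is None:
        labels = tuple(f"stim{r}" for r in range(ind.shape[1]))
    return StimulusSet(ind, labels, TR)


def write_runs(series: MultiRunSeries, stimuli: StimulusSet, out_dir) -> dict:
    """Write a dataset in the exact formats the analyze path consumes.

    One 4D NIfTI per run, a 3D mask, and an indicator-dialect timing file.
    Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    paths = {"runs": [], "mask": out / "mask.nii", "stimuli": out / "stimuli.txt"}
    for s, label in enumerate(series.run_labels):
        vol = np.zeros(series.grid_shape + (series.T,))
        vol[series.mask] = series.values[:, s]
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms((1.0, 1.0, 1.0, series.sampling_interval))
        p = out / f"run-{label}.nii"
        nib.save(img, str(p))
        paths["runs"].append(p)
    nib.save(nib.Nifti1Image(series.mask.astype(np.uint8), affine), str(paths["mask"]))
    header = " ".join(stimuli.labels)
    body = "\n".join(
        " ".join(str(int(v)) for v in row) for row in stimuli.indicators
    )
    paths["stimuli"].write_text(header + "\n" + body + "\n")
    return paths


def _fmt_df(df: tuple) -> str:
    d1, d2 = df
    d2 = int(d2) if float(d2).is_integer() else d2
    return f"({int(d1)}, {d2})"


def write_stat_maps(
    results: dict,
    series: MultiRunSeries,
    out_dir,
    levels=DEFAULT_P_LEVELS,
    affine: np.ndarray | None = None,
    write_u: bool = False,
) -> pd.DataFrame:
    """Write F/p volumes per (contrast, band) plus multi-P label maps.

    ``results`` maps contrast names to ContrastResult objects.  Filenames
    encode the contrast name and band center index; a ``manifest.tsv``
    records every file with its contrast, band center ``k_c`` and degrees
    of freedom.  Returns the manifest as a DataFrame.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    rows = []

    def save(vol: np.ndarray, name: str) -> str:
        nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), str(out / name))
        return name

    for cname in sorted(results):
        res = results[cname]
        centers = res.partition.centers
        stats_to_write = [("F", res.F), ("p", res.p)] + (
            [("U", res.U)] if write_u else []
        )
        for j, k_c in enumerate(centers):
            for stat, arr in stats_to_write:
                name = save(series.unmask(arr[j]), f"{cname}_band{k_c:03d}_{stat}.nii")
                rows.append((name, cname, k_c, stat, _fmt_df(res.df)))
        plm = multi_p_mask(res.p, levels=levels, contrast_name=cname)
        labels = series.unmask((plm.level_index + 1).astype(float), fill=0.0)
        name = save(labels, f"{cname}_plevels.nii")
        rows.append((name, cname, -1, "plevel", _fmt_df(res.df)))
    legend = "\n".join(f"{i + 1}\tP<{lev}" for i, lev in enumerate(levels))
    (out / "plevel_legend.txt").write_text(legend + "\n")
    manifest = pd.DataFrame(
        rows, columns=["filename", "contrast", "band_center_k", "statistic", "df"]
    )
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def load_config(path) -> dict:
    """Read a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: configuration must be a mapping")
    return cfg
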