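"""Between-subject z-scoring against controls and hemisphere flipping into
the ipsi/contra-lesional frame.

The published order of operations is enforced: features are z-scored per
vertex against the healthy controls *before* any hemisphere swap, so that
regional feature variation does not leak into the lesion-frame contrast.
The flip itself relies on the symmetric template's index-identity
cross-hemisphere correspondence.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = ["FeatureMatrix", "zscore_vs_controls", "flip_to_lesion_frame",
           "save_feature_matrix", "load_feature_matrix"]


@dataclass
class FeatureMatrix:
    """Subjects x (2V) matrix of one feature.

    Column blocks are [left | right] before flipping and [ipsi | contra]
    after; ``flip_log`` records per subject whether the blocks were swapped.
    """

    data: np.ndarray                     # (n_subjects, 2V)
    subject_ids: list[str]
    feature_name: str
    mask: np.ndarray                     # (V,) joint per-vertex validity
    normalization_state: str = "raw"     # 'raw' | 'zscored'
    frame: str = "left-right"            # 'left-right' | 'ipsi-contra'
    flip_log: dict[str, bool] = field(default_factory=dict)
    control_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2 or self.data.shape[1] % 2:
            raise ValueError("data must be (n_subjects, 2V)")
        if self.data.shape[0] != len(self.subject_ids):
            raise ValueError("row count must match subject_ids")
        if len(self.mask) != self.n_vertices:
            raise ValueError("mask must have V entries")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1] // 2

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def block(self, which: int) -> np.ndarray:
        V = self.n_vertices
        return self.data[:, which * V:(which + 1) * V]

    @classmethod
    def from_maps(cls, maps: dict[str, dict[str, "VertexMap"]],
                  feature_name: str) -> "FeatureMatrix":
        """Stack per-subject {'left': VertexMap, 'right': VertexMap} dicts."""
        ids = list(maps)
        rows, masks = [], []
        for sid in ids:
            left, right = maps[sid]["left"], maps[sid]["right"]
            rows.append(np.concatenate([left.values, right.values]))
            masks.append(left.mask & right.mask)
        mask = np.logical_and.reduce(masks)
        return cls(np.vstack(rows), ids, feature_name, mask)


def zscore_vs_controls(matrix: FeatureMatrix,
                       control_ids: list[str]) -> FeatureMatrix:
    """Per-vertex z-scoring against the control distribution (ddof=1).

    Vertices with zero control variance (either hemisphere) are masked with
    a warning count; z is computed in the unflipped left/right frame.
    """
    if matrix.normalization_state != "raw":
        raise ValueError("matrix is already z-scored")
    ctrl_rows = [i for i, s in enumerate(matrix.subject_ids)
                 if s in set(control_ids)]
    if len(ctrl_rows) < 2:
        raise ValueError("need >= 2 controls to z-score")
    ctrl = matrix.data[ctrl_rows]
    mu = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    V = matrix.n_vertices
    bad_col = ~(sd > 0) | ~np.isfinite(mu)
    bad_v = bad_col[:V] | bad_col[V:]
    n_newly = int((bad_v & matrix.mask).sum())
    if n_newly:
        warnings.warn(f"{n_newly} vertices masked for zero control variance",
                      stacklevel=2)
    sd_safe = np.where(bad_col, 1.0, sd)
    z = (matrix.data - mu) / sd_safe
    mask = matrix.mask & ~bad_v
    z[:, np.concatenate([~mask, ~mask])] = np.nan
    return replace(matrix, data=z, mask=mask, normalization_state="zscored",
                   control_ids=list(control_ids))


def flip_to_lesion_frame(matrix: FeatureMatrix, lesion_side: dict[str, str],
                         control_policy: str = "as-is",
                         seed: int | None = None) -> FeatureMatrix:
    """Swap hemisphere blocks so block 0 is ipsilesional for every patient.

    ``lesion_side`` maps subject id -> 'left' | 'right' | 'none'. Controls
    follow ``control_policy``: 'as-is' (left block stays first; the
    minimal-assumption default) or 'random-half' (a seeded random half of
    controls is flipped to balance hemispheres).
    """
    if matrix.normalization_state != "zscored":
        raise ValueError("flip after z-scoring (the enforced order)")
    if control_policy not in ("as-is", "random-half"):
        raise ValueError(f"unknown control_policy {control_policy!r}")
    rng = np.random.default_rng(seed)
    V = matrix.n_vertices
    out = matrix.data.copy()
    flip_log: dict[str, bool] = {}
    for i, sid in enumerate(matrix.subject_ids):
        if sid not in lesion_side:
            raise KeyError(f"no lesion side recorded for {sid}")
        side = lesion_side[sid]
        if side == "right":
            flip = True
        elif side == "left":
            flip = False
        elif side == "none":
            flip = (control_policy == "random-half"
                    and bool(rng.integers(0, 2)))
        else:
            raise ValueError(f"invalid lesion side {side!r} for {sid}")
        if flip:
            out[i] = np.concatenate([out[i, V:], out[i, :V]])
        flip_log[sid] = flip
    frame = ("left-right" if matrix.frame == "ipsi-contra"
             else "ipsi-contra")
    return replace(matrix, data=out, flip_log=flip_log, frame=frame)


def save_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """HDF5 payload + JSON sidecar (subject order, mask, flip log)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        # track_times=False keeps reruns byte-identical
        f.create_dataset("data", data=matrix.data, track_times=False)
        f.create_dataset("mask", data=matrix.mask.astype(np.uint8),
                         track_times=False)
    sidecar = {
        "subject_ids": matrix.subject_ids,
        "feature_name": matrix.feature_name,
        "normalization_state": matrix.normalization_state,
        "frame": matrix.frame,
        "flip_log": matrix.flip_log,
        "control_ids": matrix.control_ids,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        mask = f["mask"][()].astype(bool)
    return FeatureMatrix(data, meta["subject_ids"], meta["feature_name"],
                         mask, meta["normalization_state"], meta["frame"],
                         meta["flip_log"], meta["control_ids"])
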