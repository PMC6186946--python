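"""Hippocampal volumetry and normalized-FLAIR quantification from label
masks, with the group and within-patient lateralization statistics.

Segmentation itself is out of scope: any binary NIfTI label volume is
accepted (the synthetic generator supplies ellipsoidal stand-ins). FLAIR
normalization shares the subject's cortical context (GMpeak, B), so
hippocampal RI is on the same scale as the cortical maps.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .features import FlairNormalizationContext
from .surface_core import IntensityVolume

__all__ = ["HippocampusMeasures", "hippo_volume", "hippo_flair",
           "measures_to_lesion_frame", "hippo_group_model",
           "hippo_paired_tests"]


@dataclass
class HippocampusMeasures:
    subject_id: str
    side: str                            # 'left' | 'right'
    volume_mm3: float
    mean_ri: float
    icv_mm3: float

    def __post_init__(self):
        if self.volume_mm3 <= 0:
            raise ValueError("hippocampal volume must be positive")


def hippo_volume(mask: IntensityVolume) -> float:
    """Voxel count times voxel volume (mm^3); empty masks are an error."""
    m = np.asarray(mask.grid) > 0
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty hippocampal mask")
    return n * mask.voxel_volume_mm3


def hippo_flair(mask: IntensityVolume, flair: IntensityVolume,
                ctx: FlairNormalizationContext) -> float:
    """Mean normalized FLAIR (RI) over the mask voxels."""
    m = np.asarray(mask.grid) > 0
    if not np.allclose(mask.affine, flair.affine) or \
            mask.grid.shape != flair.grid.shape:
        raise ValueError("mask and FLAIR grids do not match")
    vals = np.asarray(flair.grid, float)[m]
    return float(np.mean((vals - ctx.gm_peak) / (ctx.gm_peak - ctx.boundary)))


def measures_to_lesion_frame(measures: pd.DataFrame,
                             meta: pd.DataFrame) -> pd.DataFrame:
    """Wide per-subject table with ipsi/contra columns.

    Controls keep left as the 'ipsi' slot (side-matched comparisons are
    formed explicitly in :func:`hippo_group_model`).
    """
    meta_ix = meta.set_index("id")
    rows = []
    for sid, grp in measures.groupby("id", sort=False):
        side = meta_ix.loc[sid, "lesion_side"]
        by = grp.set_index("side")
        ipsi = side if side in ("left", "right") else "left"
        contra = "right" if ipsi == "left" else "left"
        rows.append(dict(
            id=sid, group=meta_ix.loc[sid, "group"],
            age_years=meta_ix.loc[sid, "age_years"],
            icv_mm3=float(by.loc[ipsi, "icv_mm3"]),
            lesion_side=side,
            vol_ipsi=float(by.loc[ipsi, "volume_mm3"]),
            vol_contra=float(by.loc[contra, "volume_mm3"]),
            ri_ipsi=float(by.loc[ipsi, "mean_ri"]),
            ri_contra=float(by.loc[contra, "mean_ri"])))
    return pd.DataFrame(rows)


def _ols_group_term(y: np.ndarray, meta: pd.DataFrame) -> dict:
    X = np.column_stack([
        np.ones(len(meta)),
        (meta.group == "patient").to_numpy(float),
        meta.age_years.to_numpy(float),
        meta.icv_mm3.to_numpy(float),
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates in hippocampal model")
    fit = sm.OLS(y, X).fit()
    return {"t": float(fit.tvalues[1]), "p": float(fit.pvalues[1]),
            "beta": float(fit.params[1]), "df": int(fit.df_resid)}


def hippo_group_model(measures: pd.DataFrame,
                      meta: pd.DataFrame) -> dict[str, dict]:
    """OLS ``measure ~ group + age + ICV`` for volume and RI.

    For each of the ipsi- and contra-lesional sides, patients are compared
    against the side-matched control hippocampus (a patient's ipsilesional
    left hippocampus is compared to control left hippocampi, etc.), which
    keeps left/right anatomical asymmetry out of the group term.
    """
    wide = measures_to_lesion_frame(measures, meta)
    pat = wide[wide.group == "patient"]
    ctrl = wide[wide.group == "control"]
    if len(pat) < 3 or len(ctrl) < 3:
        raise ValueError("need >= 3 subjects per group")
    ctrl_by_side = {s: measures[(measures.id.isin(ctrl.id))
                                & (measures.side == s)] for s in
                    ("left", "right")}
    out: dict[str, dict] = {}
    for which, vcol, rcol in (("ipsi", "vol_ipsi", "ri_ipsi"),
                              ("contra", "vol_contra", "ri_contra")):
        rows = []
        for _, r in pat.iterrows():
            side = (r.lesion_side if which == "ipsi"
                    else ("right" if r.lesion_side == "left" else "left"))
            rows.append(dict(group="patient", age_years=r.age_years,
                             icv_mm3=r.icv_mm3, vol=r[vcol], ri=r[rcol],
                             side=side))
        for s in ("left", "right"):
            sub = ctrl_by_side[s].set_index("id")
            for cid in sub.index:
                rows.append(dict(group="control",
                                 age_years=float(ctrl.set_index("id")
                                                 .loc[cid, "age_years"]),
                                 icv_mm3=float(sub.loc[cid, "icv_mm3"]),
                                 vol=float(sub.loc[cid, "volume_mm3"]),
                                 ri=float(sub.loc[cid, "mean_ri"]), side=s))
        tbl = pd.DataFrame(rows)
        out[f"volume_{which}"] = _ols_group_term(tbl.vol.to_numpy(), tbl)
        out[f"flair_{which}"] = _ols_group_term(tbl.ri.to_numpy(), tbl)
    return out


def hippo_paired_tests(measures: pd.DataFrame,
                       meta: pd.DataFrame) -> dict[str, dict]:
    """Within-patient paired t of (ipsi - contra) volume and RI."""
    wide = measures_to_lesion_frame(measures, meta)
    pat = wide[wide.group == "patient"]
    if len(pat) < 2:
        raise ValueError("need >= 2 patients for a paired test")
    out = {}
    for name, a, b in (("volume", "vol_ipsi", "vol_contra"),
                       ("flair", "ri_ipsi", "ri_contra")):
        diff = pat[a].to_numpy() - pat[b].to_numpy()
        if np.allclose(diff.std(ddof=1), 0):
            out[name] = {"t": np.inf * np.sign(diff.mean()) if
                         diff.mean() != 0 else 0.0,
                         "p": 0.0 if diff.mean() != 0 else 1.0,
                         "df": len(diff) - 1, "degenerate": True}
            continue
        t, p = stats.ttest_rel(pat[a], pat[b])
        out[name] = {"t": float(t), "p": float(p), "df": len(diff) - 1,
                     "degenerate": False}
    return out
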