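"""Region-level biomarker evaluation: ROC curves and clinical correlations.

Per-subject region values are means of the normalized, smoothed
connectivity-density map over a cluster's member voxels.  Discrimination
between patients and controls is summarized by the rank (Mann–Whitney) AUC
with midrank tie handling, oriented so AUC >= 0.5, and an operating cutoff
chosen by Youden's J, reported midway between adjacent observed values.
All evaluation is in-sample, mirroring common practice for small
case-control neuroimaging studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionValues",
    "RocResult",
    "extract_region_means",
    "roc",
    "combine_regions",
    "pearson_corr",
    "summarize_roc_table",
]


@dataclass
class RegionValues:
    """Per-subject mean map value over one region, with group labels."""

    region_id: str
    values: np.ndarray
    labels: np.ndarray  # "patient" / "control" per subject

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.shape != self.labels.shape:
            raise ValueError("values and labels must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("region values must be finite")


@dataclass
class RocResult:
    """In-sample ROC summary for one region-level discriminator."""

    region_id: str
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str  # "patients_higher" | "patients_lower"


def extract_region_means(
    subject_maps: np.ndarray, member_voxels: np.ndarray, labels, region_id: str = ""
) -> RegionValues:
    """Mean map value over a cluster's voxels, per subject.

    ``subject_maps`` is an (n_subjects, x, y, z) stack; ``member_voxels``
    an (k, 3) index array from a :class:`~fcdens.inference.ClusterResult`.
    """
    mv = np.asarray(member_voxels)
    if mv.size == 0:
        raise ValueError("empty cluster")
    maps = np.asarray(subject_maps, dtype=np.float64)
    vals = maps[:, mv[:, 0], mv[:, 1], mv[:, 2]].mean(axis=1)
    return RegionValues(region_id=region_id, values=vals, labels=np.asarray(labels))


def _auc_midrank(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann–Whitney AUC with ties counted half, via midranks."""
    allv = np.concatenate([pos, neg])
    ranks = stats.rankdata(allv)
    n1, n0 = len(pos), len(neg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc(region: RegionValues, positive: str = "patient") -> RocResult:
    """ROC analysis of one region discriminator.

    AUC is the probability a random patient's value ranks above a random
    control's (ties half weight), reported oriented so AUC >= 0.5 with the
    direction recorded.  The cutoff maximizes Youden's J = sensitivity +
    specificity - 1 over thresholds placed midway between adjacent observed
    values; sensitivity/specificity are empirical per-class fractions at
    that cutoff.
    """
    labels = region.labels
    pos = region.values[labels == positive]
    neg = region.values[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    auc = _auc_midrank(pos, neg)
    if auc >= 0.5:
        direction, sgn = "patients_higher", 1.0
    else:
        direction, sgn = "patients_lower", -1.0
        auc = 1.0 - auc
    vp, vn = sgn * pos, sgn * neg
    allv = np.unique(np.concatenate([vp, vn]))
    if len(allv) == 1:
        cuts = np.array([allv[0]])
    else:
        mids = (allv[:-1] + allv[1:]) / 2.0
        cuts = np.concatenate(([allv[0] - 1.0], mids, [allv[-1] + 1.0]))
    best = None
    for c in cuts:
        sens = float(np.mean(vp > c))
        spec = float(np.mean(vn <= c))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    _, cut, sens, spec = best
    return RocResult(
        region_id=region.region_id,
        auc=auc,
        cutoff=float(sgn * cut),
        sensitivity=sens,
        specificity=spec,
        direction=direction,
    )


def combine_regions(regions: list[RegionValues], region_id: str = "combined") -> RegionValues:
    """Combined per-subject score over several regions.

    Each region is first oriented so that higher values are more
    patient-like (regions where patients score lower are sign-flipped),
    then the per-subject mean across regions is taken.  Order-invariant.
    """
    if len(regions) < 2:
        raise ValueError("need >= 2 regions to combine")
    labels = regions[0].labels
    n = len(labels)
    for r in regions[1:]:
        if len(r.labels) != n or not np.array_equal(r.labels, labels):
            raise ValueError("regions must cover the same subjects in order")
    oriented = []
    for r in regions:
        pos = r.values[labels == "patient"].mean()
        neg = r.values[labels != "patient"].mean()
        oriented.append(r.values if pos >= neg else -r.values)
    return RegionValues(
        region_id=region_id,
        values=np.mean(oriented, axis=0),
        labels=labels,
    )


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson r with the two-tailed p from the exact t transform.

    p comes from ``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of
    freedom; |r| = 1 returns p = 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need aligned samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a given Pearson r and sample size (t transform)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def summarize_roc_table(results: list[RocResult]) -> dict:
    """Mean, sample sd and range of AUC / sensitivity / specificity.

    Sensitivity and specificity are summarized in percent.  A single
    result yields sd 0 and a zero-width range.
    """
    if not results:
        raise ValueError("need >= 1 ROC result")

    def _summ(vals):
        v = np.asarray(vals, dtype=float)
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        return {
            "mean": float(v.mean()),
            "sd": sd,
            "min": float(v.min()),
            "max": float(v.max()),
        }

    return {
        "auc": _summ([r.auc for r in results]),
        "sensitivity_pct": _summ([100.0 * r.sensitivity for r in results]),
        "specificity_pct": _summ([100.0 * r.specificity for r in results]),
    }


def roc_table(results: list[RocResult]) -> pd.DataFrame:
    """ROC report: region, AUC, sensitivity %, specificity %, cutoff."""
    return pd.DataFrame(
        [
            {
                "region": r.region_id,
                "auc": r.auc,
                "sensitivity_pct": 100.0 * r.sensitivity,
                "specificity_pct": 100.0 * r.specificity,
                "cutoff": r.cutoff,
                "direction": r.direction,
            }
            for r in results
        ]
    )
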