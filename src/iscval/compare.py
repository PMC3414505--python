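"""Agreement measures between ISC and GLM outputs.

Two measures are used.  For unthresholded maps, the Pearson correlation C
between the ISC statistic and the (by default absolute) GLM z statistic over
brain voxels: both strong activations and strong de-activations are expected
to raise inter-subject correlation, so |Z| is the natural comparand.  For
thresholded maps, the Dice index D = 2|A n B| / (|A| + |B|) between the
binarised activation sets, computed over the full volume (for the standard
2 mm space that is 91*109*91 = 902,629 voxels); for sparse maps the Dice
index is asymptotically equal to Cohen's kappa, so D is interpreted with
the conventional Landis-Koch agreement categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MNI152_SHAPE",
    "corr_measure",
    "dice",
    "kappa_category",
    "ComparisonReport",
    "build_report",
]

#: Standard-space 2 mm grid used for full-volume Dice bookkeeping.
MNI152_SHAPE = (91, 109, 91)

_CATEGORIES = [
    (0.0, "Slight agreement"),
    (0.2, "Fair agreement"),
    (0.4, "Moderate agreement"),
    (0.6, "Substantial agreement"),
    (0.8, "Almost perfect agreement"),
]


def corr_measure(
    zmap: np.ndarray,
    iscmap: np.ndarray,
    mask: np.ndarray | None = None,
    use_abs: bool = True,
) -> float:
    """Pearson correlation C between the GLM and ISC statistic maps.

    Computed across in-mask voxels between ``|Z|`` (or signed Z when
    ``use_abs`` is off) and the ISC statistic.  Voxels that are NaN in
    either map are dropped; a constant map raises.
    """
    zmap = np.asarray(zmap, dtype=float)
    iscmap = np.asarray(iscmap, dtype=float)
    if zmap.shape != iscmap.shape:
        raise ValueError("maps must share a grid")
    z = zmap.ravel()
    r = iscmap.ravel()
    keep = np.isfinite(z) & np.isfinite(r)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool).ravel()
    if not keep.any():
        raise ValueError("empty comparison mask")
    z = np.abs(z[keep]) if use_abs else z[keep]
    r = r[keep]
    if np.ptp(z) == 0 or np.ptp(r) == 0:
        raise ValueError("constant map: correlation measure undefined")
    return float(np.corrcoef(z, r)[0, 1])


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice index 2|A n B| / (|A| + |B|) of two binary maps.

    Computed over the full volume.  Raises when both maps are empty (the
    index is undefined, not 0 or 1).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    na = int(a.sum())
    nb = int(b.sum())
    if na + nb == 0:
        raise ValueError("both maps empty: Dice index undefined")
    return 2.0 * int((a & b).sum()) / (na + nb)


def kappa_category(d: float) -> str:
    """Landis-Koch agreement label for a Dice/kappa value.

    Bins are left-closed ([0.6, 0.8) is substantial); 1.0 belongs to
    "Almost perfect agreement"; values below 0 mean no agreement.
    """
    if not -1.0 <= d <= 1.0:
        raise ValueError("agreement value must lie in [-1, 1]")
    if d < 0:
        return "No agreement"
    label = _CATEGORIES[0][1]
    for lo, name in _CATEGORIES:
        if d >= lo:
            label = name
    return label


@dataclass
class ComparisonReport:
    """Per-task, per-threshold agreement table.

    ``correlation`` holds C per task (plus an average); ``dice_table`` holds
    D per (task, q) with row/column averages; ``categories`` labels each D.
    """

    correlation: pd.Series
    dice_table: pd.DataFrame
    categories: pd.DataFrame
    use_abs: bool = True
    n_voxels: int | None = None
    extras: dict = field(default_factory=dict)


def build_report(
    runs: Mapping[str, Mapping],
    q_levels,
    mask: np.ndarray | None = None,
    use_abs: bool = True,
) -> ComparisonReport:
    """Tabulate C and D across tasks and thresholds.

    ``runs`` maps a task name to a mapping with keys ``zmap``, ``iscmap``,
    ``glm_active`` and ``isc_active`` (the latter two map q -> binary map).
    Missing entries leave NaN gaps rather than failing the whole report.
    """
    q_levels = list(q_levels)
    corr = {}
    dtable = pd.DataFrame(index=list(runs), columns=q_levels, dtype=float)
    n_vox = None
    for task, maps in runs.items():
        zmap = maps.get("zmap")
        iscmap = maps.get("iscmap")
        if zmap is not None and iscmap is not None:
            corr[task] = corr_measure(zmap, iscmap, mask=mask, use_abs=use_abs)
            n_vox = int(np.asarray(zmap).size)
        else:
            corr[task] = np.nan
        for q in q_levels:
            ga = maps.get("glm_active", {}).get(q)
            ia = maps.get("isc_active", {}).get(q)
            if ga is not None and ia is not None:
                dtable.loc[task, q] = dice(ga, ia)
    correlation = pd.Series(corr, name="C")
    correlation.loc["Average"] = correlation.mean()
    dtable.loc["Average"] = dtable.mean()
    dtable["Average"] = dtable.mean(axis=1)
    categories = dtable.map(
        lambda v: kappa_category(v) if np.isfinite(v) else ""
    )
    return ComparisonReport(
        correlation=correlation,
        dice_table=dtable,
        categories=categories,
        use_abs=use_abs,
        n_voxels=n_vox,
    )
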