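"""In-vivo organ displacement arithmetic.

Per-patient box-ROI translations (dx, dy, dz = left-right, anterior-
posterior, superior-inferior, mm) between the maximum-inhale and
maximum-exhale bins of each modality (CT, axial 5-bin MR, coronal 10-bin
MR), their Euclidean norms, per-direction means across patients, and
CT-minus-MR difference tables.

All table cells use exact decimal half-up rounding at one decimal place
(binary-float rounding would turn 4.85 into 4.8). Difference tables are
computed from the rounded (printed) per-direction means, which is the only
combination rule consistent with the published summaries. Kidney values are
averages of the left and right kidney, so a kidney per-patient Euclidean
norm is an average of two norms and is *not* derivable from the averaged
components; such cells are carried as data, not recomputed.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .errors import DegenerateRoiError

MODALITIES = ("CT", "AX_MR", "COR_MR")
DIRECTIONS = ("dx", "dy", "dz", "euclidean")


def _dec(x) -> Decimal:
    return Decimal(str(x))


def _round1(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def euclidean(dx: float, dy: float, dz: float) -> float:
    """3-D Euclidean displacement, mm, decimal half-up to one decimal."""
    total = _dec(dx) ** 2 + _dec(dy) ** 2 + _dec(dz) ** 2
    return _round1(total.sqrt())


def direction_means(values: Iterable[float]) -> float:
    """Arithmetic mean of printed per-patient values, half-up to one decimal."""
    vals = [_dec(v) for v in values]
    if not vals:
        raise ValueError("need at least one value")
    return _round1(sum(vals) / len(vals))


def load_displacements(path=None) -> pd.DataFrame:
    """Per-patient displacement fixture (printed per-patient table values).

    Columns: patient_id, organ, modality, dx_mm, dy_mm, dz_mm,
    euclidean_mm (as printed), derivable_euclidean (False where the printed
    norm is an average of left/right kidney norms).
    """
    if path is None:
        path = resources.files("motion4d.data") / "organ_displacements.csv"
    return pd.read_csv(path)


def load_printed_means(path=None) -> pd.DataFrame:
    """Printed per-direction means (the bold summary column of the published
    per-patient tables)."""
    if path is None:
        path = resources.files("motion4d.data") / "organ_means_printed.csv"
    return pd.read_csv(path)


def compute_means(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Recompute per-direction means from per-patient values (half-up, one
    decimal), including the per-patient Euclidean norms where derivable."""
    rows = []
    for (organ, modality), g in per_patient.groupby(["organ", "modality"], observed=True):
        rows.append(
            {
                "organ": organ,
                "modality": modality,
                "dx": direction_means(g["dx_mm"]),
                "dy": direction_means(g["dy_mm"]),
                "dz": direction_means(g["dz_mm"]),
                "euclidean": direction_means(g["euclidean_mm"]),
            }
        )
    return pd.DataFrame(rows)


def euclidean_consistency(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Check each derivable printed per-patient Euclidean value against the
    norm of its printed components; mismatches are flagged, not corrected."""
    rows = []
    for _, r in per_patient.iterrows():
        if not r.get("derivable_euclidean", True):
            continue
        computed = euclidean(r["dx_mm"], r["dy_mm"], r["dz_mm"])
        rows.append(
            {
                "patient_id": r["patient_id"],
                "organ": r["organ"],
                "modality": r["modality"],
                "printed": r["euclidean_mm"],
                "computed": computed,
                "consistent": abs(computed - r["euclidean_mm"]) < 0.05,
            }
        )
    return pd.DataFrame(rows)


def mean_consistency(per_patient: pd.DataFrame, printed_means: pd.DataFrame) -> pd.DataFrame:
    """Compare recomputed means against the printed summary means.

    Several published means are inconsistent with their printed per-patient
    inputs (they were evidently computed from unrounded sources); those cells
    are flagged here rather than silently matched.
    """
    computed = compute_means(per_patient).set_index(["organ", "modality"])
    printed = printed_means.set_index(["organ", "modality"])
    rows = []
    for key in computed.index:
        for col in DIRECTIONS:
            comp = computed.loc[key, col]
            prin = printed.loc[key, col]
            rows.append(
                {
                    "organ": key[0],
                    "modality": key[1],
                    "direction": col,
                    "printed": prin,
                    "computed_from_printed_inputs": comp,
                    "consistent": abs(comp - prin) < 0.05,
                }
            )
    return pd.DataFrame(rows)


def modality_difference_table(printed_means: pd.DataFrame) -> pd.DataFrame:
    """CT-minus-MR differences per organ and direction, from 1-decimal means.

    A positive value means the CT displacement was larger.
    """
    means = printed_means.set_index(["organ", "modality"])
    required = set(MODALITIES)
    rows = []
    for organ in printed_means["organ"].unique():
        have = {m for o, m in means.index if o == organ}
        if not required <= have:
            raise ValueError(f"missing modalities for organ {organ!r}: {required - have}")
        for mr in ("AX_MR", "COR_MR"):
            row = {"organ": organ, "comparison": f"CT-{mr}"}
            for col in DIRECTIONS:
                diff = _dec(means.loc[(organ, "CT"), col]) - _dec(means.loc[(organ, mr), col])
                row[col] = _round1(diff)
            rows.append(row)
    return pd.DataFrame(rows)


def roi_translation(
    inhale_volume: np.ndarray,
    exhale_volume: np.ndarray,
    box_roi: tuple[slice, slice, slice],
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    max_shift_vox: int = 8,
) -> tuple[float, float, float]:
    """Rigid translation (mm) of a box ROI from exhale to inhale.

    Maximizes the zero-normalized cross-correlation of the ROI over integer
    shifts, then refines each axis to sub-voxel precision by quadratic
    interpolation of the correlation peak.
    """
    if inhale_volume.shape != exhale_volume.shape:
        raise ValueError("volumes must share a grid")
    roi = np.asarray(inhale_volume, dtype=float)[box_roi]
    if roi.std() <= 1e-12:
        raise DegenerateRoiError("ROI has no intensity structure")
    roi = (roi - roi.mean()) / roi.std()

    pad = max_shift_vox
    search_sl = tuple(
        slice(max(s.start - pad, 0), min(s.stop + pad, n))
        for s, n in zip(box_roi, exhale_volume.shape)
    )
    search = np.asarray(exhale_volume, dtype=float)[search_sl]
    # zero-normalized local correlation via FFT: correlate the standardized
    # ROI against the search region, normalizing by local windowed moments
    kernel = roi[::-1, ::-1, ::-1]
    num = fftconvolve(search, kernel, mode="valid")
    ones = np.ones_like(roi)
    local_sum = fftconvolve(search, ones[::-1, ::-1, ::-1], mode="valid")
    local_sq = fftconvolve(search**2, ones[::-1, ::-1, ::-1], mode="valid")
    nvox = roi.size
    local_var = np.clip(local_sq - local_sum**2 / nvox, 1e-12, None)
    ncc = num / np.sqrt(local_var * nvox)

    peak = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    offset0 = [search_sl[ax].start - box_roi[ax].start for ax in range(3)]
    shift = []
    for ax in range(3):
        i = peak[ax]
        delta = 0.0
        if 0 < i < ncc.shape[ax] - 1:
            idx_m = list(peak)
            idx_p = list(peak)
            idx_m[ax] -= 1
            idx_p[ax] += 1
            ym, y0, yp = ncc[tuple(idx_m)], ncc[peak], ncc[tuple(idx_p)]
            denom = ym - 2 * y0 + yp
            if abs(denom) > 1e-12:
                delta = float(np.clip(0.5 * (ym - yp) / denom, -0.5, 0.5))
        # displacement of the structure from exhale to inhale is the negative
        # of where the matching window sits in the exhale volume
        shift.append(-(offset0[ax] + i + delta) * voxel_size[ax])
    return tuple(shift)
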