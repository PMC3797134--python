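"""ROI quantification, reference-tissue normalization and group comparison.

Per animal, tumor MTR asymmetry is averaged over that animal's tumor ROIs
(one representative value per animal when there are multiple nodules) and
normalized by subtracting the spinal-cord reference ROI's asymmetry at every
offset; the reference removes the intrinsically asymmetric background MT/NOE
contribution shared by all tissues.  Groups are compared offset-by-offset
with a two-sample, two-tailed, pooled-variance Student's t-test at alpha =
0.05 (no multiple-testing adjustment across offsets by default, mirroring
the per-frequency testing convention of the underlying study; a Holm
adjustment flag is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import AsymmetrySpectrum
from .spectra import ROI  # re-exported: ROI geometry lives with the spectra

__all__ = ["ROI", "AnimalResult", "TTestResult", "animal_summary",
           "group_compare", "summary_from_stats", "build_group_table"]


@dataclass
class AnimalResult:
    """Per-animal, per-offset ROI summary.

    ``corrected = tumor - cord`` holds exactly, offset-wise.
    """

    animal_id: str
    group: str
    offsets: np.ndarray
    tumor: np.ndarray  # mean over the animal's tumor ROIs
    cord: np.ndarray
    corrected: np.ndarray

    def value_at(self, offset: float, quantity: str = "corrected") -> float:
        arr = getattr(self, quantity)
        idx = np.flatnonzero(np.abs(self.offsets - offset) <= 1e-6)
        if idx.size == 0:
            raise ValueError(f"offset {offset} ppm not available")
        return float(arr[idx[0]])


@dataclass
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def animal_summary(animal_id: str, group: str,
                   tumor_spectra: list[AsymmetrySpectrum],
                   cord_spectrum: AsymmetrySpectrum) -> AnimalResult:
    """Combine one animal's tumor and cord asymmetry spectra.

    Tumor value is the unweighted mean across tumor ROIs (multiple nodules
    give one representative value); corrected value subtracts the cord
    reference offset-wise.
    """
    if not tumor_spectra:
        raise ValueError(f"animal {animal_id!r}: no tumor ROI spectra")
    if cord_spectrum is None:
        raise ValueError(f"animal {animal_id!r}: cord reference ROI missing; "
                         "normalization impossible")
    offsets = tumor_spectra[0].offsets
    for spec in tumor_spectra[1:]:
        if not np.allclose(spec.offsets, offsets):
            raise ValueError("tumor ROI spectra on different offset grids")
    if not np.allclose(cord_spectrum.offsets, offsets):
        raise ValueError("cord spectrum on a different offset grid")
    tumor = np.mean([s.values for s in tumor_spectra], axis=0)
    cord = cord_spectrum.values.copy()
    return AnimalResult(animal_id=animal_id, group=group,
                        offsets=offsets.copy(), tumor=tumor, cord=cord,
                        corrected=tumor - cord)


def _pooled_ttest(a: np.ndarray, b: np.ndarray) -> TTestResult:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    # ptp, not var: catastrophic cancellation makes var of identical floats
    # come out ~1e-35 rather than exactly zero
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if np.isclose(np.mean(a), np.mean(b)):
            return TTestResult(0.0, 1.0, degenerate=True)
        sign = 1.0 if np.mean(a) > np.mean(b) else -1.0
        return TTestResult(sign * np.inf, 0.0, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), float(p))


def group_compare(animals: list[AnimalResult], offset: float,
                  quantity: str = "corrected",
                  groups: tuple[str, str] | None = None) -> TTestResult:
    """Two-sample pooled-variance Student's t-test at one offset.

    ``quantity`` selects the per-animal value (``tumor``, ``cord`` or
    ``corrected``); groups are inferred from the animal records unless
    given explicitly.
    """
    if groups is None:
        seen = list(dict.fromkeys(a.group for a in animals))
        if len(seen) != 2:
            raise ValueError(f"expected exactly 2 groups, found {seen}")
        groups = (seen[0], seen[1])
    a = [x.value_at(offset, quantity) for x in animals if x.group == groups[0]]
    b = [x.value_at(offset, quantity) for x in animals if x.group == groups[1]]
    return _pooled_ttest(np.array(a), np.array(b))


def summary_from_stats(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int) -> TTestResult:
    """Pooled two-tailed t-test from printed summary statistics.

    Identical to ``group_compare`` applied to any raw data with these
    summaries; lets published mean ± SD values be checked without raw data.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if np.isclose(mean1, mean2):
            return TTestResult(0.0, 1.0, degenerate=True)
        return TTestResult(np.sign(mean1 - mean2) * np.inf, 0.0,
                           degenerate=True)
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=True)
    return TTestResult(float(t), float(p))


def build_group_table(animals: list[AnimalResult], alpha: float = 0.05,
                      holm: bool = False) -> pd.DataFrame:
    """Per-offset group statistics for raw (tumor) and corrected asymmetry.

    One row per (offset, quantity): n, mean and SD per group (SD with n-1
    denominator), pooled t, two-tailed p, and a significance flag at
    ``alpha``.  ``holm`` applies a Holm step-down adjustment across offsets
    within each quantity (off by default).  Values are in percent.
    """
    groups = list(dict.fromkeys(a.group for a in animals))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    offsets = animals[0].offsets
    rows = []
    for quantity in ("tumor", "corrected"):
        for offset in offsets:
            vals = {g: np.array([a.value_at(offset, quantity)
                                 for a in animals if a.group == g])
                    for g in groups}
            res = _pooled_ttest(vals[groups[0]], vals[groups[1]])
            row = {"offset_ppm": float(offset), "quantity": quantity,
                   "t": res.t, "p": res.p, "degenerate": res.degenerate}
            for g in groups:
                row[f"n_{g}"] = len(vals[g])
                row[f"mean_{g}"] = 100.0 * float(np.mean(vals[g]))
                # identical values report SD exactly 0 (cancellation guard)
                sd = 0.0 if np.ptp(vals[g]) == 0 else float(np.std(vals[g],
                                                                   ddof=1))
                row[f"sd_{g}"] = 100.0 * sd
            rows.append(row)
    table = pd.DataFrame(rows)
    if holm:
        for quantity in ("tumor", "corrected"):
            sel = table["quantity"] == quantity
            p = table.loc[sel, "p"].to_numpy()
            order = np.argsort(p)
            adj = np.empty_like(p)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (len(p) - rank) * p[idx])
                adj[idx] = min(running, 1.0)
            table.loc[sel, "p_adjusted"] = adj
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["significant"] = table["p"] < alpha
    return table
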