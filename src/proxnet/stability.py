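"""Mantel matrix-correlation tests and day-to-day network stability.

A stable social group keeps the same nearest-neighbour structure from one
day to the next. Stability is quantified by the Mantel test: the Pearson
correlation between corresponding off-diagonal cells of two same-labeled
association matrices, with significance from jointly permuting the rows and
columns of one matrix. The day-to-day series correlates each consecutive
pair of daily NN matrices (plus first vs last as a long-range check); the
group's stability index is the mean of the *consecutive* correlations only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd

from .neighbors import build_nn_matrix, filter_by_nnd, from_observed_neighbors, nearest_neighbor_pairs
from .scan_data import ScanDataset

__all__ = ["MantelResult", "StabilitySeries", "mantel", "daily_series", "stability_index"]

_TAILS = ("greater", "less", "two-sided")


@dataclass(frozen=True)
class MantelResult:
    """Result of one Mantel test.

    ``r`` is the Pearson correlation over off-diagonal cells; ``p`` the
    permutation p-value with the +1 correction (sampled null) or the exact
    enumeration fraction; ``permutations`` the number of non-identity
    permutations drawn, or the full factorial count when exact.
    """

    r: float
    p: float
    permutations: int
    seed: int | None
    tail: str = "greater"
    exact: bool = False


def _offdiag_vectors(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mask = ~np.eye(a.shape[0], dtype=bool)
    return a[mask], b[mask], mask


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise ValueError("constant matrix: Mantel r undefined")
    return float(xc @ yc) / denom


def _as_array(m, labels=None):
    if isinstance(m, pd.DataFrame):
        if labels is not None and (list(m.index) != labels or list(m.columns) != labels):
            raise ValueError("matrix labels differ between the two matrices")
        return m.to_numpy(dtype=float), list(m.index)
    arr = np.asarray(m, dtype=float)
    return arr, labels


def mantel(
    a,
    b,
    permutations: int = 10_000,
    seed: int | None = None,
    tail: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel test between two square, identically labeled matrices.

    Parameters
    ----------
    a, b
        Square arrays or DataFrames with matching labels. Diagonals are
        ignored.
    permutations
        Number of random joint row/column permutations of ``b`` (>= 99).
    seed
        Seed for the permutation generator; required for reproducibility.
    tail
        ``"greater"`` (default; positive correlation implies stability),
        ``"less"`` or ``"two-sided"``.
    exact
        Enumerate all n! permutations instead of sampling (small n only);
        the p-value is then the exact fraction of permutations at least as
        extreme, the identity included.

    The sampled p-value is ``(1 + extreme) / (1 + permutations)`` and thus
    honors the lower bound ``1 / (permutations + 1)``.
    """
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    arr_a, labels = _as_array(a)
    arr_b, _ = _as_array(b, labels)
    if arr_a.shape != arr_b.shape or arr_a.ndim != 2 or arr_a.shape[0] != arr_a.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    size = arr_a.shape[0]
    va, vb, mask = _offdiag_vectors(arr_a, arr_b)
    r_obs = _pearson(va, vb)

    def extreme(r_perm: np.ndarray) -> np.ndarray:
        if tail == "greater":
            return r_perm >= r_obs - 1e-12
        if tail == "less":
            return r_perm <= r_obs + 1e-12
        return np.abs(r_perm) >= abs(r_obs) - 1e-12

    if exact:
        if size > 8:
            raise ValueError("exact enumeration is limited to n <= 8")
        rs = []
        for perm in iter_permutations(range(size)):
            p = np.array(perm)
            rs.append(_pearson(va, arr_b[np.ix_(p, p)][mask]))
        rs = np.array(rs)
        count = int(extreme(rs).sum())
        total = math.factorial(size)
        return MantelResult(r=r_obs, p=count / total, permutations=total, seed=None, tail=tail, exact=True)

    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    xc = va - va.mean()
    xnorm = math.sqrt(float(xc @ xc))
    count = 0
    chunk = 2_000
    done = 0
    while done < permutations:
        k = min(chunk, permutations - done)
        perms = np.array([rng.permutation(size) for _ in range(k)])
        bp = arr_b[perms[:, :, None], perms[:, None, :]][:, mask]  # (k, n(n-1))
        bc = bp - bp.mean(axis=1, keepdims=True)
        denom = xnorm * np.sqrt((bc * bc).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r_perm = np.where(denom > 0, bc @ xc / np.where(denom > 0, denom, 1.0), 0.0)
        count += int(extreme(r_perm).sum())
        done += k
    p = (1 + count) / (1 + permutations)
    return MantelResult(r=r_obs, p=p, permutations=permutations, seed=seed, tail=tail, exact=False)


@dataclass
class StabilitySeries:
    """Day-to-day Mantel series for one group.

    ``comparisons`` holds ``(day_a, day_b, MantelResult)`` for consecutive
    retained days; ``first_last`` the long-range first-vs-last comparison.
    ``mean_consecutive_r`` averages the consecutive correlations only — the
    first-vs-last entry is excluded by convention.
    """

    days: list
    comparisons: list
    first_last: tuple | None
    skipped_days: list = field(default_factory=list)
    matrices: dict = field(default_factory=dict)

    @property
    def consecutive_r(self) -> list:
        return [res.r for _, _, res in self.comparisons]

    @property
    def mean_consecutive_r(self) -> float:
        return stability_index(self.consecutive_r)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"days": f"{a}~{b}", "r": res.r, "p": res.p, "permutations": res.permutations}
            for a, b, res in self.comparisons
        ]
        if self.first_last is not None:
            a, b, res = self.first_last
            rows.append({"days": f"{a}~{b}", "r": res.r, "p": res.p, "permutations": res.permutations})
        return pd.DataFrame(rows)


def stability_index(consecutive_r) -> float:
    """Mean of a series of consecutive-day matrix correlations."""
    rs = list(consecutive_r)
    if not rs:
        raise ValueError("no consecutive correlations to average")
    return float(np.mean(rs))


def daily_series(
    ds: ScanDataset,
    max_nnd: float | None = None,
    nnd_strict: bool = False,
    permutations: int = 10_000,
    seed: int = 0,
    symmetrize: bool = True,
    tail: str = "greater",
) -> StabilitySeries:
    """Build daily NN matrices and Mantel-correlate consecutive days.

    One NN count matrix per observation day (symmetrized by default — the
    directed tally is available behind the flag), a Mantel test on each
    consecutive pair of retained days, plus first vs last. Days yielding no
    NN pairs are skipped with a warning and listed in ``skipped_days``.
    Per-comparison permutation seeds are derived reproducibly from ``seed``.
    """
    all_days = ds.days
    if len(all_days) < 2:
        raise ValueError("need at least two observation days")
    mats, skipped = {}, []
    for day in all_days:
        sub = ScanDataset(
            ds.records[ds.records["day"] == day].reset_index(drop=True),
            list(ds.individuals),
            list(ds.facilities),
            ds.mode,
            dict(ds.meta),
        )
        pairs = nearest_neighbor_pairs(sub) if ds.mode == "coordinate" else from_observed_neighbors(sub)
        if max_nnd is not None:
            pairs = filter_by_nnd(pairs, max_nnd, strict=nnd_strict)
        if len(pairs) == 0:
            warnings.warn(f"day {day}: no NN pairs; day skipped in the stability series", stacklevel=2)
            skipped.append(day)
            continue
        m = build_nn_matrix(pairs, ds.individuals, threshold=max_nnd)
        mats[day] = m.symmetrized().to_numpy(dtype=float) if symmetrize else m.counts.astype(float)
    days = [d for d in all_days if d in mats]
    if len(days) < 2:
        raise ValueError("fewer than two days with NN pairs")
    seed_rng = np.random.default_rng(seed)
    child_seeds = seed_rng.integers(0, 2**31 - 1, size=len(days))
    comparisons = []
    for k in range(len(days) - 1):
        a, b = days[k], days[k + 1]
        res = mantel(mats[a], mats[b], permutations=permutations, seed=int(child_seeds[k]), tail=tail)
        comparisons.append((a, b, res))
    fl = mantel(mats[days[0]], mats[days[-1]], permutations=permutations, seed=int(child_seeds[-1]), tail=tail)
    first_last = (days[0], days[-1], fl)
    return StabilitySeries(days=days, comparisons=comparisons, first_last=first_last, skipped_days=skipped, matrices=mats)
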