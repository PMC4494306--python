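"""Signed association structures from NN count matrices.

A dyad is *significantly attracted* when it is observed as a nearest-
neighbour pair more often than expected under an independence null, and
*significantly avoidant* when less often. Cell-wise evidence is the
standardized residual of the contingency table,

    SR = (o - e) / sqrt(e),

with |SR| > 1.96 (the two-sided 5% normal point) flagging a cell. The SR
matrix is split into a positive matrix (SR where SR > t, else 0) and a
negative matrix (-SR where SR < -t, else 0); both are non-negative weighted
matrices with disjoint supports and feed the sociogram builders in
:mod:`proxnet.network`.

The same machinery applies unchanged to 2-mode individual x facility tables
(affiliation networks), which have no structural-zero diagonal.

Null model
----------
Expected counts default to the Pearson contingency convention
``e[i, j] = row_i * col_j / n`` with the diagonal forced to zero. Because
the diagonal of an NN matrix is structurally zero, the plain margins product
leaves a little expected mass on the diagonal; an iterative-proportional-
fitting variant (``method="ipf"``) fits the off-diagonal table to the
margins exactly and is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .neighbors import NNCountMatrix
from .scan_data import ScanDataset, joint_visible_counts, visible_counts

__all__ = [
    "SignedAssociation",
    "AffiliationAssociation",
    "expected_counts",
    "standardized_residuals",
    "sign_split",
    "associate",
    "simple_ratio_index",
    "affiliation_association",
]

DEFAULT_THRESHOLD = 1.96


@dataclass
class SignedAssociation:
    """Observed/expected/SR and sign-split matrices for one group.

    All matrices are I x I with a zero diagonal, ordered like
    ``individuals``. ``positive`` and ``negative`` are non-negative with
    disjoint non-zero supports.
    """

    individuals: list
    observed: np.ndarray
    expected: np.ndarray
    sr: np.ndarray
    positive: np.ndarray
    negative: np.ndarray
    threshold: float
    n: int

    def matrix(self, name: str) -> pd.DataFrame:
        return pd.DataFrame(getattr(self, name), index=self.individuals, columns=self.individuals)


@dataclass
class AffiliationAssociation:
    """2-mode analogue: individuals (rows) x facilities (columns)."""

    individuals: list
    facilities: list
    observed: np.ndarray
    expected: np.ndarray
    sr: np.ndarray
    positive: np.ndarray
    negative: np.ndarray
    threshold: float
    n: int

    def matrix(self, name: str) -> pd.DataFrame:
        return pd.DataFrame(getattr(self, name), index=self.individuals, columns=self.facilities)


def expected_counts(
    counts: np.ndarray | NNCountMatrix,
    method: str = "margins",
    zero_diagonal: bool = True,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Expected cell counts under row/column independence.

    ``method="margins"`` is the Pearson chi-square convention
    ``e = outer(row totals, column totals) / n``. ``method="ipf"``
    iteratively rescales rows and columns (with the diagonal held at zero
    when ``zero_diagonal``) until both margins are reproduced; this removes
    the slight bias of the plain product when the diagonal is structural.
    """
    if isinstance(counts, NNCountMatrix):
        counts = counts.counts
    o = np.asarray(counts, dtype=float)
    if zero_diagonal and o.shape[0] == o.shape[1]:
        o = o.copy()
        np.fill_diagonal(o, 0.0)
    n = o.sum()
    if n <= 0:
        raise ValueError("zero grand total: expected counts undefined")
    r = o.sum(axis=1)
    c = o.sum(axis=0)
    if method == "margins":
        e = np.outer(r, c) / n
    elif method == "ipf":
        e = np.ones_like(o)
        if zero_diagonal and o.shape[0] == o.shape[1]:
            np.fill_diagonal(e, 0.0)
        e[r == 0.0, :] = 0.0
        e[:, c == 0.0] = 0.0
        for _ in range(max_iter):
            rs = e.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                e *= np.where(rs > 0, r / np.where(rs > 0, rs, 1.0), 0.0)[:, None]
            cs = e.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                e *= np.where(cs > 0, c / np.where(cs > 0, cs, 1.0), 0.0)[None, :]
            if (
                np.abs(e.sum(axis=1) - r).max() <= tol * max(n, 1.0)
                and np.abs(e.sum(axis=0) - c).max() <= tol * max(n, 1.0)
            ):
                break
    else:
        raise ValueError(f"unknown expected-count method {method!r}")
    if zero_diagonal and e.shape[0] == e.shape[1]:
        np.fill_diagonal(e, 0.0)
    return e


def standardized_residuals(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Cell-wise (o - e)/sqrt(e); cells with e = 0 and o = 0 give SR = 0.

    A cell with e = 0 but o > 0 has no defined residual and raises, naming
    the cell.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected shapes differ")
    undefined = (e == 0) & (o > 0)
    if undefined.any():
        i, j = np.argwhere(undefined)[0]
        raise ValueError(f"cell ({i}, {j}): observed {o[i, j]:g} with expected 0 — SR undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        sr = np.where(e > 0, (o - e) / np.sqrt(np.where(e > 0, e, 1.0)), 0.0)
    return sr


def sign_split(sr: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> tuple[np.ndarray, np.ndarray]:
    """Split an SR matrix into non-negative positive/negative weight matrices.

    Strictly greater than the threshold: a residual of exactly 1.96 is not
    significant under the documented rule. The negative matrix carries
    ``-SR`` so both outputs are weights >= 0.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sr = np.asarray(sr, dtype=float)
    positive = np.where(sr > threshold, sr, 0.0)
    negative = np.where(sr < -threshold, -sr, 0.0)
    return positive, negative


def _bonferroni_threshold(n_cells: int, alpha: float = 0.05) -> float:
    return float(norm.isf(alpha / 2.0 / n_cells))


def associate(
    m: NNCountMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    method: str = "margins",
    bonferroni: bool = False,
    alpha: float = 0.05,
) -> SignedAssociation:
    """Full signed association structure from a directed NN count matrix.

    With ``bonferroni=True`` the SR threshold is raised to the two-sided
    normal point at ``alpha`` divided by the number of off-diagonal cells
    (no correction is applied by default).
    """
    o = m.counts.astype(float)
    e = expected_counts(o, method=method)
    sr = standardized_residuals(o, e)
    size = len(m.individuals)
    if bonferroni:
        threshold = _bonferroni_threshold(size * (size - 1), alpha)
    positive, negative = sign_split(sr, threshold)
    return SignedAssociation(
        individuals=list(m.individuals),
        observed=m.counts.copy(),
        expected=e,
        sr=sr,
        positive=positive,
        negative=negative,
        threshold=threshold,
        n=int(m.n_pairs),
    )


def simple_ratio_index(
    m: NNCountMatrix,
    scans_visible: pd.Series | dict | np.ndarray,
    joint: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Simple ratio association index per dyad.

    The numerator is the symmetrized NN count ``c[i,j] + c[j,i]``. The
    denominator is twice the number of scans in which both dyad members
    were observed (each such scan contributes two focal observations), so a
    dyad that is mutually nearest neighbour in every joint scan scores 1.
    When only per-individual visibility totals are available the joint count
    is approximated by ``min(n_i, n_j)`` — exact whenever all animals stay
    visible in every scan, the regime in which the NN matrix and the index
    rank dyads identically. Pass ``joint`` (e.g. from
    :func:`proxnet.scan_data.joint_visible_counts`) for the exact form.

    Dyads with no joint observations score 0 with a warning.
    """
    ids = list(m.individuals)
    if isinstance(scans_visible, dict):
        nvis = np.array([scans_visible[a] for a in ids], dtype=float)
    elif isinstance(scans_visible, pd.Series):
        nvis = scans_visible.reindex(ids).to_numpy(dtype=float)
    else:
        nvis = np.asarray(scans_visible, dtype=float)
    if (nvis <= 0).any():
        raise ValueError("scans_visible must be positive for every individual")
    if joint is None:
        joint_arr = np.minimum.outer(nvis, nvis)
    elif isinstance(joint, pd.DataFrame):
        joint_arr = joint.reindex(index=ids, columns=ids).to_numpy(dtype=float)
    else:
        joint_arr = np.asarray(joint, dtype=float)
    sym = (m.counts + m.counts.T).astype(float)
    denom = 2.0 * joint_arr
    zero = (denom == 0) & ~np.eye(len(ids), dtype=bool)
    if (sym[zero] >= 0).any() and zero.any():
        warnings.warn("dyads with no joint observations score 0 in the simple ratio index", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(denom > 0, sym / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(sri, 0.0)
    return pd.DataFrame(sri, index=ids, columns=ids)


def affiliation_association(ds: ScanDataset, threshold: float = DEFAULT_THRESHOLD) -> AffiliationAssociation:
    """2-mode individual x nearest-facility association.

    ``observed[i, f]`` counts the scans in which individual ``i``'s nearest
    facility was ``f``; expected counts, residuals and the sign split use
    exactly the 1-mode machinery (no diagonal to exclude).
    """
    rec = ds.records
    with_fac = rec[rec["visible"] & rec["facility"].notna()]
    if len(with_fac) == 0:
        raise ValueError("dataset carries no facility records")
    ids, facs = list(ds.individuals), list(ds.facilities)
    tab = pd.crosstab(with_fac["individual"], with_fac["facility"])
    tab = tab.reindex(index=ids, columns=facs, fill_value=0)
    o = tab.to_numpy(dtype=float)
    e = expected_counts(o, zero_diagonal=False)
    sr = standardized_residuals(o, e)
    positive, negative = sign_split(sr, threshold)
    return AffiliationAssociation(
        individuals=ids,
        facilities=facs,
        observed=o.astype(int),
        expected=e,
        sr=sr,
        positive=positive,
        negative=negative,
        threshold=threshold,
        n=int(o.sum()),
    )


# convenience: the two visibility helpers are re-exported where users expect them
__all__ += ["visible_counts", "joint_visible_counts"]
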