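"""Nearest neighbours, nearest-neighbour distances and NN count matrices.

The nearest neighbour (NN) of a focal animal at one scan is the conspecific
at minimum Euclidean distance among the other visible individuals of that
scan. The relation is *not* symmetric: A's nearest neighbour may have a
different nearest neighbour of its own. Tallying, over all scans, how often
each (focal, neighbour) ordered pair occurs gives the directed NN count
matrix that all downstream association analysis is built on.

Pair tables are plain DataFrames with columns ``day, scan, focal, neighbor,
nnd`` (``nnd`` in metres, NaN for datasets where the neighbour was recorded
directly and distances were never measured).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .scan_data import IntegrityError, ScanDataset

__all__ = [
    "PAIR_COLUMNS",
    "NNCountMatrix",
    "NNDStats",
    "nearest_neighbor_pairs",
    "from_observed_neighbors",
    "nnd_statistics",
    "filter_by_nnd",
    "build_nn_matrix",
]

log = logging.getLogger(__name__)

PAIR_COLUMNS = ["day", "scan", "focal", "neighbor", "nnd"]


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "day": pd.Series(dtype=int),
            "scan": pd.Series(dtype=int),
            "focal": pd.Series(dtype=object),
            "neighbor": pd.Series(dtype=object),
            "nnd": pd.Series(dtype=float),
        }
    )


@dataclass
class NNCountMatrix:
    """Directed focal(row) x neighbour(column) count matrix.

    Attributes
    ----------
    individuals
        Ordered identifiers; rows/columns follow this order.
    counts
        I x I non-negative integer array with a zero diagonal.
    n_pairs
        Grand total of counts (one per retained NN pair observation).
    threshold
        The NND cut-off (metres) the pairs were filtered at, or None for
        the unlimited matrix.
    """

    individuals: list
    counts: np.ndarray
    n_pairs: int
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        size = len(self.individuals)
        if self.counts.shape != (size, size):
            raise ValueError("counts shape does not match the individuals list")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if np.diagonal(self.counts).any():
            raise ValueError("diagonal of an NN count matrix must be zero")
        if int(self.counts.sum()) != int(self.n_pairs):
            raise ValueError("n_pairs does not equal the sum of counts")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.individuals, columns=self.individuals)

    def symmetrized(self) -> pd.DataFrame:
        """counts + counts.T — the undirected dyadic tally."""
        m = self.counts + self.counts.T
        return pd.DataFrame(m, index=self.individuals, columns=self.individuals)


@dataclass(frozen=True)
class NNDStats:
    n: int
    mean: float
    sd: float
    min: float
    max: float


def nearest_neighbor_pairs(ds: ScanDataset) -> pd.DataFrame:
    """One NN pair per visible individual per scan, from coordinates.

    For every scan with at least two visible located individuals, each
    individual is paired with the other individual at minimum Euclidean
    distance. Exact distance ties are broken towards the smallest
    identifier in sorted order so runs are reproducible. Scans with fewer
    than two visible individuals yield no pairs and are logged.
    """
    if ds.mode != "coordinate":
        raise ValueError("nearest_neighbor_pairs needs a coordinate-mode dataset")
    rec = ds.records
    located = rec[rec["visible"] & rec["x"].notna()]
    rows = []
    for (day, scan), grp in located.groupby(["day", "scan"], sort=True):
        if len(grp) < 2:
            log.debug("scan (day=%s, scan=%s) has <2 visible individuals; no pairs", day, scan)
            continue
        ids = grp["individual"].to_numpy()
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        dist = cdist(xy, xy)
        np.fill_diagonal(dist, np.inf)
        for k in range(len(ids)):
            dmin = dist[k].min()
            candidates = ids[dist[k] == dmin]
            rows.append((day, scan, ids[k], min(candidates), float(dmin)))
    if not rows:
        return _empty_pairs()
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def from_observed_neighbors(ds: ScanDataset) -> pd.DataFrame:
    """Pairs from directly recorded nearest neighbours (no distances).

    Records without a recorded neighbour (animal not seen, or noted with a
    not-seen token at read time) are skipped. A neighbour that is not in the
    dataset's individual list is an integrity error.
    """
    if ds.mode != "neighbor":
        raise ValueError("from_observed_neighbors needs a neighbor-mode dataset")
    rec = ds.records
    has_nb = rec[rec["visible"] & rec["neighbor"].notna()]
    unknown = set(has_nb["neighbor"]) - set(ds.individuals)
    if unknown:
        raise IntegrityError(f"recorded neighbors not in the individuals list: {sorted(unknown)}")
    out = has_nb[["day", "scan", "individual", "neighbor"]].rename(columns={"individual": "focal"})
    out = out.reset_index(drop=True)
    out["nnd"] = np.nan
    return out[PAIR_COLUMNS]


def nnd_statistics(pairs: pd.DataFrame, ddof: int = 0) -> NNDStats:
    """Mean, sd, min and max of nearest-neighbour distance over all pairs.

    ``ddof=0`` (population sd) is the default convention; pass ``ddof=1``
    for the sample sd.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs: NND statistics undefined")
    nnd = pairs["nnd"].to_numpy(dtype=float)
    if np.isnan(nnd).any():
        raise ValueError("NND absent on some pairs (neighbor-mode data?)")
    return NNDStats(
        n=len(nnd),
        mean=float(nnd.mean()),
        sd=float(nnd.std(ddof=ddof)),
        min=float(nnd.min()),
        max=float(nnd.max()),
    )


def filter_by_nnd(pairs: pd.DataFrame, max_nnd: float, strict: bool = False) -> pd.DataFrame:
    """Keep pairs with nnd <= max_nnd (or < max_nnd when ``strict``).

    Field conventions differ: "a maximum NND of 5 meters" is inclusive,
    "less than 1 meter" is strict — hence the flag. Monotone in ``max_nnd``
    and the identity at infinity.
    """
    nnd = pairs["nnd"]
    keep = nnd < max_nnd if strict else nnd <= max_nnd
    return pairs[keep].reset_index(drop=True)


def build_nn_matrix(pairs: pd.DataFrame, individuals: list, threshold: float | None = None) -> NNCountMatrix:
    """Tally a pair table into a directed NN count matrix.

    ``counts[f, n]`` is the number of pairs with focal ``f`` and neighbour
    ``n``; the grand total equals the number of pairs.
    """
    idx = {a: k for k, a in enumerate(individuals)}
    counts = np.zeros((len(individuals), len(individuals)), dtype=int)
    try:
        rows = np.fromiter((idx[f] for f in pairs["focal"]), dtype=int, count=len(pairs))
        cols = np.fromiter((idx[n] for n in pairs["neighbor"]), dtype=int, count=len(pairs))
    except KeyError as err:
        raise IntegrityError(f"pair member {err} not in the individuals list") from None
    np.add.at(counts, (rows, cols), 1)
    return NNCountMatrix(list(individuals), counts, n_pairs=len(pairs), threshold=threshold)
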