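"""Shared fixtures: tiny hand-built datasets and graphs."""

import numpy as np
import pandas as pd
import pytest

from proxnet.scan_data import COLUMNS, ScanDataset


def make_dataset(rows, individuals=None, facilities=None, mode="coordinate", meta=None):
    """Build a ScanDataset from (day, scan, individual, x, y, neighbor, facility, behavior, visible) tuples."""
    records = pd.DataFrame(rows, columns=COLUMNS)
    records["x"] = records["x"].astype(float)
    records["y"] = records["y"].astype(float)
    if individuals is None:
        individuals = list(dict.fromkeys(records["individual"]))
    if facilities is None:
        facilities = list(dict.fromkeys(f for f in records["facility"] if f is not None))
    return ScanDataset(records, individuals, facilities, mode, dict(meta or {}))


@pytest.fixture
def dyad_dataset():
    """Two individuals at (0,0) and (3,4) for one scan: mutual NN at 5 m."""
    return make_dataset(
        [
            (1, 1, "A", 0.0, 0.0, None, None, None, True),
            (1, 1, "B", 3.0, 4.0, None, None, None, True),
        ]
    )


@pytest.fixture
def collinear_dataset():
    """Three collinear points at x = 0, 1, 3: the NN relation is asymmetric."""
    return make_dataset(
        [
            (1, 1, "P0", 0.0, 0.0, None, None, None, True),
            (1, 1, "P1", 1.0, 0.0, None, None, None, True),
            (1, 1, "P2", 3.0, 0.0, None, None, None, True),
        ]
    )


@pytest.fixture
def hen_dataset():
    """Neighbor-mode dataset with facilities, no coordinates."""
    rows = []
    hens = [f"Hen{i}" for i in range(1, 5)]
    rng = np.random.default_rng(5)
    for day in (1, 2):
        for scan in range(1, 11):
            for hen in hens:
                nb = rng.choice([h for h in hens if h != hen])
                fac = rng.choice(["Feed", "Perch"])
                rows.append((day, scan, hen, np.nan, np.nan, nb, fac, None, True))
    return make_dataset(rows, mode="neighbor")


def random_scan_dataset(rng, n_individuals=10, days=2, scans=5, arena=30.0, p_invisible=0.0):
    """Uniform random placements; used against brute-force oracles."""
    rows = []
    names = [f"I{k:02d}" for k in range(n_individuals)]
    for day in range(1, days + 1):
        for scan in range(1, scans + 1):
            for k, name in enumerate(names):
                if rng.random() < p_invisible:
                    rows.append((day, scan, name, np.nan, np.nan, None, None, None, False))
                else:
                    x, y = rng.uniform(0, arena, size=2)
                    rows.append((day, scan, name, x, y, None, None, None, True))
    return make_dataset(rows, individuals=names)
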