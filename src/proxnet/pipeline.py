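"""End-to-end pipeline: scan file in, signed-network artifact bundle out.

The pipeline is a pure function of (input file, config, seed). It writes a
fixed set of plain-text artifacts into the output directory:

``nn_matrix.csv``
    directed focal x neighbour count matrix (after any NND filter)
``nnd_stats.csv``
    NND summary (coordinate-mode inputs only)
``sr_matrix.csv``
    standardized residuals
``network_positive.graphml`` / ``network_negative.graphml``
    signed sociograms
``node_metrics_positive.csv`` / ``node_metrics_negative.csv``
    per-node degree/betweenness/farness/cutpoint/block tables with averages
``stability.csv``
    day-to-day Mantel series (consecutive pairs plus first vs last)
``affiliation_sr.csv``
    2-mode individual x facility residuals (when facilities are recorded)
``comparison.csv``
    one cross-network comparison row
``run_log.json``
    versions, seed, parameter echo and stage counters (no timestamps, so
    reruns are byte-identical)
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx
import numpy
import pandas
import scipy
import yaml

from . import __version__
from .association import affiliation_association, associate
from .neighbors import build_nn_matrix, filter_by_nnd, from_observed_neighbors, nearest_neighbor_pairs, nnd_statistics
from .network import build_graph, export_graph, node_table
from .report import compare_networks, render_report
from .scan_data import filter_daylight, read_scans, uniform_scan_hours
from .stability import daily_series

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]

STAGES = ("read", "neighbors", "associate", "network", "stability", "affiliation", "report", "log")


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it and exit codes are stage-coded."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.code = STAGES.index(stage) + 1


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from a YAML file."""

    input: str
    outdir: str
    label: str = "group"
    schema: dict = field(default_factory=dict)
    daylight: tuple | None = None  # (start_hour, end_hour)
    session_start_hour: float = 6.0
    scan_interval_minutes: float = 10.0
    max_nnd: float | None = None
    nnd_strict: bool = False
    sr_threshold: float = 1.96
    expected_method: str = "margins"
    symmetrize_daily: bool = True
    permutations: int = 1000
    seed: int = 17

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        io_block = raw.pop("io", {})
        for key in ("schema", "session_start_hour", "scan_interval_minutes"):
            if key in io_block:
                raw[key] = io_block[key]
        if "daylight" in raw and raw["daylight"] is not None:
            raw["daylight"] = tuple(raw["daylight"])
        return cls(**raw)


def _float_csv(df, path):
    df.to_csv(path, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns a mapping of artifact names to paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    counters: dict = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, str(err)) from err
        return deco

    @stage("read")
    def ds():
        data = read_scans(cfg.input, schema=cfg.schema)
        if cfg.daylight is not None:
            hours = uniform_scan_hours(
                int(data.records["scan"].max()), cfg.session_start_hour, cfg.scan_interval_minutes
            )
            data = filter_daylight(data, cfg.daylight[0], cfg.daylight[1], hours)
        return data

    @stage("neighbors")
    def matrix():
        if ds.mode == "coordinate":
            pairs = nearest_neighbor_pairs(ds)
            counters["n_pairs_unlimited"] = len(pairs)
            if cfg.max_nnd is not None:
                pairs = filter_by_nnd(pairs, cfg.max_nnd, strict=cfg.nnd_strict)
            stats = nnd_statistics(pairs)
            pandas.DataFrame([asdict(stats)]).to_csv(outdir / "nnd_stats.csv", index=False, float_format="%.10g")
            artifacts["nnd_stats"] = outdir / "nnd_stats.csv"
        else:
            pairs = from_observed_neighbors(ds)  # NND stages skipped: distances were never measured
        counters["n_pairs"] = len(pairs)
        m = build_nn_matrix(pairs, ds.individuals, threshold=cfg.max_nnd)
        _float_csv(m.to_dataframe(), outdir / "nn_matrix.csv")
        artifacts["nn_matrix"] = outdir / "nn_matrix.csv"
        return m

    @stage("associate")
    def assoc():
        a = associate(matrix, threshold=cfg.sr_threshold, method=cfg.expected_method)
        _float_csv(a.matrix("sr"), outdir / "sr_matrix.csv")
        artifacts["sr_matrix"] = outdir / "sr_matrix.csv"
        return a

    @stage("network")
    def graphs():
        out = {}
        for sign in ("positive", "negative"):
            g = build_graph(assoc, sign)
            gpath = outdir / f"network_{sign}.graphml"
            export_graph(g, gpath, "graphml")
            artifacts[f"network_{sign}"] = gpath
            tpath = outdir / f"node_metrics_{sign}.csv"
            _float_csv(node_table(g), tpath)
            artifacts[f"node_metrics_{sign}"] = tpath
            out[sign] = g
        return out

    @stage("stability")
    def series():
        s = daily_series(
            ds,
            max_nnd=cfg.max_nnd,
            nnd_strict=cfg.nnd_strict,
            permutations=cfg.permutations,
            seed=cfg.seed,
            symmetrize=cfg.symmetrize_daily,
        )
        s.to_dataframe().to_csv(outdir / "stability.csv", index=False, float_format="%.10g")
        artifacts["stability"] = outdir / "stability.csv"
        return s

    @stage("affiliation")
    def _affiliation():
        if not ds.facilities:
            return None
        aff = affiliation_association(ds, threshold=cfg.sr_threshold)
        _float_csv(aff.matrix("sr"), outdir / "affiliation_sr.csv")
        artifacts["affiliation_sr"] = outdir / "affiliation_sr.csv"
        return aff

    @stage("report")
    def _report():
        rows = compare_networks([(cfg.label, assoc, series)])
        render_report(rows, outdir / "comparison.csv", outdir / "comparison.txt")
        artifacts["comparison"] = outdir / "comparison.csv"

    @stage("log")
    def _log():
        log = {
            "proxnet": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
            "seed": cfg.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
            "counters": counters,
            "individuals": list(ds.individuals),
            "facilities": list(ds.facilities),
            "mode": ds.mode,
        }
        path = outdir / "run_log.json"
        path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
        artifacts["run_log"] = path

    return {k: str(v) for k, v in artifacts.items()}
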