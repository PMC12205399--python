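"""Result writers, configuration round-trip, and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .psa import PSAResults

__all__ = ["save_config", "config_hash", "RunManifest", "write_results",
           "summary_table"]

# Table layout: outcome columns in presentation order; costs in thousands
_TABLE_COLS = [
    ("od_fatal", "overdoses_fatal_5y_per_1000", 1.0),
    ("od_nonfatal", "overdoses_nonfatal_5y_per_1000", 1.0),
    ("od_total", "overdoses_total_5y_per_1000", 1.0),
    ("deaths", "deaths_5y_per_1000", 1.0),
    ("qalys", "lifetime_qalys_pp", 1.0),
    ("cost_hc", "lifetime_cost_hc_pp_thousands", 1e-3),
    ("cost_housing", "lifetime_cost_housing_pp_thousands", 1e-3),
    ("cost_total", "lifetime_cost_total_pp_thousands", 1e-3),
]


def save_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    n_draws: int
    scenario: str
    package_version: str
    timestamp: str

    @classmethod
    def create(cls, cfg: dict, seed: int, n_draws: int,
               scenario: str) -> "RunManifest":
        from . import __version__
        return cls(config_hash=config_hash(cfg), seed=seed, n_draws=n_draws,
                   scenario=scenario, package_version=__version__,
                   timestamp=datetime.now(timezone.utc).isoformat())

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def _fmt(mean: float, lo: float, hi: float, digits: int = 1) -> str:
    return f"{mean:.{digits}f} ({lo:.{digits}f}-{hi:.{digits}f})"


def summary_table(results: dict[str, PSAResults]) -> pd.DataFrame:
    """Scenario-by-outcome table: one row per scenario arm, columns ordered
    as fatal/nonfatal/total overdoses, deaths, QALYs, health-care/housing/
    total costs (thousands), ICER (thousands per QALY); each outcome appears
    as ``mean (lo-hi)`` text plus raw numeric columns."""
    rows = []
    for name, res in sorted(results.items()):
        if res.n_draws == 0:
            continue
        summ = res.summary()
        arms = ([("status_quo", "sq"), ("housing", "hi")] if name == "base"
                else [("housing", "hi")])
        for arm, p in arms:
            row: dict[str, object] = {
                "scenario": name, "arm": arm, "n_draws": res.n_draws,
                "icer_thousands_per_qaly": "NA", "icer_mean": float("nan")}
            for key, label, scale in _TABLE_COLS:
                s = summ.loc[f"{p}_{key}"]
                row[label] = _fmt(s["mean"] * scale, s["lo"] * scale,
                                  s["hi"] * scale)
                row[f"{label}_mean"] = s["mean"] * scale
            rows.append(row)
        inc: dict[str, object] = {
            "scenario": name, "arm": "incremental", "n_draws": res.n_draws}
        s = summ.loc["icer"]
        inc["icer_thousands_per_qaly"] = _fmt(s["mean"] / 1e3, s["lo"] / 1e3,
                                              s["hi"] / 1e3)
        inc["icer_mean"] = s["mean"] / 1e3
        for col in ("d_cost", "d_qaly"):
            s = summ.loc[col]
            digits = 0 if col == "d_cost" else 2
            inc[col] = _fmt(s["mean"], s["lo"], s["hi"], digits)
            inc[f"{col}_mean"] = s["mean"]
        rows.append(inc)
    return pd.DataFrame(rows)


def write_results(results: dict[str, PSAResults] | pd.DataFrame,
                  outdir: str | Path, formats: set[str] = frozenset({"csv"}),
                  stem: str = "scenario_table") -> list[Path]:
    """Write PSA results (scenario table + per-draw frames) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if isinstance(results, pd.DataFrame):
        table = results
        per_draw: dict[str, PSAResults] = {}
    else:
        table = summary_table(results)
        per_draw = results
    if "csv" in formats:
        p = outdir / f"{stem}.csv"
        table.to_csv(p, index=False)
        written.append(p)
        for name, res in per_draw.items():
            p = outdir / f"draws_{name}.csv"
            res.draws.to_csv(p, index=False)
            written.append(p)
    if "json" in formats:
        p = outdir / f"{stem}.json"
        table.to_json(p, orient="records", indent=2)
        written.append(p)
    return written
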