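"""Result serialisation, manifests and table exports."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import pandas as pd

from .params import ParameterSet
from .engine import RunResult
from .cea import CeaFrontier

__version__ = "0.1.0"


def config_hash(params: ParameterSet, extra: dict | None = None) -> str:
    """Stable hash of a parameter set (plus run options)."""
    payload = {"params": params.to_dict(), "extra": extra or {}}
    blob = json.dumps(payload, sort_keys=True, default=_json_default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _json_default(o):
    try:
        return o.item()
    except AttributeError:
        return list(o)


@dataclass
class RunManifest:
    """Provenance record making any reported number traceable."""

    config_hash: str
    seed: int
    strategies: list[str]
    software_version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    notes: str = ""

    def to_dict(self) -> dict:
        return dict(config_hash=self.config_hash, seed=self.seed,
                    strategies=list(self.strategies),
                    software_version=self.software_version,
                    timestamp=self.timestamp, notes=self.notes)


def make_manifest(params: ParameterSet, seed: int, strategies, notes: str = "") -> RunManifest:
    return RunManifest(config_hash=config_hash(params), seed=seed,
                       strategies=[getattr(s, "name", str(s)) for s in strategies],
                       notes=notes)


# ---------------------------------------------------------------------------
# table exports
# ---------------------------------------------------------------------------


def intermediate_table(results: list[RunResult]) -> pd.DataFrame:
    """Intermediate-outcome counts, one column per strategy."""
    cols = {}
    for r in results:
        col = dict(r.counts)
        col.update({f"stage_{g}_pct_10y": v
                    for g, v in r.stage_distribution_10y.items()})
        cols[r.strategy] = col
    return pd.DataFrame(cols)


def cea_table(frontier: CeaFrontier) -> pd.DataFrame:
    """Cost-utility results table: totals, incrementals and classification."""
    rows = []
    for e in frontier.entries:
        if e.classification == "frontier":
            icur = "" if e.icur is None else f"{e.icur:.0f}"
            label = icur
        else:
            label = ("Dominated" if e.classification == "strongly_dominated"
                     else "Weakly dominated")
        rows.append({
            "Strategy": e.label,
            "Total Cost": e.cost,
            "Total Effect": e.effect,
            "Incremental Cost": e.incremental_cost,
            "Incremental Effect": e.incremental_effect,
            "ICUR/classification": label,
        })
    return pd.DataFrame(rows)


def export_tables(results: list[RunResult], frontier: CeaFrontier | None,
                  outdir) -> list[str]:
    """Write the intermediate-outcome and cost-utility CSVs; idempotent."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    p1 = outdir / "intermediate_outcomes.csv"
    intermediate_table(results).to_csv(p1)
    written.append(str(p1))
    if frontier is not None:
        p2 = outdir / "cost_utility.csv"
        cea_table(frontier).to_csv(p2, index=False)
        written.append(str(p2))
    return written


def save_results_json(results: list[RunResult], manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump({"manifest": manifest.to_dict(),
                   "results": [r.to_dict() for r in results]}, fh, indent=2)
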