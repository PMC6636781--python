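"""Structured outputs: time-series CSVs, outcome JSON records, seed
manifests.  CSV headers are stable across runs (see column lists below)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .lattice import OutcomeSummary, TimeseriesRecord

BACTERIA_COLUMNS = ["iteration", "strain", "resistance", "lysogen", "count"]
TOTALS_COLUMNS = [
    "iteration",
    "n_bacteria",
    "n_lysogens",
    "free_functional",
    "free_transducing",
    "cum_transductions",
    "cum_inductions",
]


def write_timeseries(ts: TimeseriesRecord, directory: str | Path, prefix: str = "") -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ts.bacteria.reindex(columns=BACTERIA_COLUMNS).to_csv(
        d / f"{prefix}bacteria.csv", index=False
    )
    ts.totals.reindex(columns=TOTALS_COLUMNS).to_csv(
        d / f"{prefix}totals.csv", index=False
    )


def outcome_dict(o: OutcomeSummary) -> dict:
    return {
        "bacteria_survived": o.bacteria_survived,
        "phage_survived": o.phage_survived,
        "joint_survival": o.joint_survival,
        "final_iteration": o.final_iteration,
        "seed": o.seed,
    }


def write_outcomes(
    outcomes: Sequence[OutcomeSummary],
    fractions: dict[str, float],
    path: str | Path,
) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        json.dumps(
            {
                "n_replicates": len(outcomes),
                "survival_fractions": fractions,
                "replicates": [outcome_dict(o) for o in outcomes],
            },
            indent=2,
        )
    )


def write_seed_manifest(master_seed: int, n_reps: int, path: str | Path) -> None:
    """Record the replicate-seed derivation (master seed + counter)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        json.dumps(
            {
                "master_seed": master_seed,
                "n_replicates": n_reps,
                "derivation": "numpy SeedSequence([master_seed, replicate_index])",
            },
            indent=2,
        )
    )
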