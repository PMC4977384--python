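"""Result serialization: tables as CSV/JSON plus a run manifest.

Every CLI run drops a ``manifest.json`` next to its outputs recording the
command, the configuration source, a hash of the fully resolved
parameter bundle, the seed (when randomness is involved) and the package
version, so identical inputs are verifiably identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .analyses import ComparisonResult
from .parameters import ParameterBundle, bundle_to_dict


@dataclass(frozen=True)
class RunManifest:
    command: str
    config: str  # path or "defaults"
    parameter_hash: str
    seed: int | None
    timestamp: str
    version: str

    def write(self, directory: str | Path) -> Path:
        path = Path(directory) / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def parameter_hash(bundle: ParameterBundle) -> str:
    """Deterministic hash of the fully resolved parameter bundle."""
    canonical = json.dumps(bundle_to_dict(bundle), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def make_manifest(
    command: str, bundle: ParameterBundle, config: str | None, seed: int | None = None
) -> RunManifest:
    from . import __version__

    return RunManifest(
        command=command,
        config=config or "defaults",
        parameter_hash=parameter_hash(bundle),
        seed=seed,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        version=__version__,
    )


def comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """One row per cohort × horizon, usual-care absolutes plus increments."""
    rows = []
    for r in results:
        rows.append(
            {
                "cohort": r.cohort_label,
                "horizon_months": r.horizon_months,
                "usual_cost": r.usual.cost,
                "usual_life_years": r.usual.life_years,
                "usual_admissions": r.usual.admissions,
                "incremental_cost": r.incremental.cost,
                "incremental_life_years": r.incremental.life_years,
                "incremental_admissions": r.incremental.admissions,
                "saving": r.saving,
            }
        )
    return pd.DataFrame(rows)


def write_table(frame: pd.DataFrame, directory: str | Path, stem: str) -> list[Path]:
    """Write a table as both CSV and JSON; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{stem}.csv"
    json_path = directory / f"{stem}.json"
    frame.to_csv(csv_path, index=False, lineterminator="\r\n")
    json_path.write_text(frame.to_json(orient="records", indent=2) + "\n")
    return [csv_path, json_path]
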