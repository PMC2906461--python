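"""End-to-end reproducible runs: manifest, stage composition, outputs.

A run simulates the community (or consumes a measured steady-state table),
generates observations, quantifies the members by qPCR, allocates fluxes and
emits the balance report plus a per-day composition table.  Outputs are
deterministic for a fixed seed; timestamps go to the log only, so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig, default_config, load_config
from .io import atomic_write, write_frame_csv, write_state_csv
from .qpcr import community_composition, quantify_plate
from .simulate import default_scenario, make_upset_scenario, observe, simulate_scenario
from .trophic import build_report

__all__ = ["RunManifest", "run_pipeline"]

log = logging.getLogger("chemobalance")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce one pipeline run."""

    seed: int
    config_path: str | None = None
    upset: str | None = None
    duration_days: float = 40.0
    package_version: str = __version__
    input_sha256: dict[str, str] = field(default_factory=dict)
    created: str | None = None  # informational only; excluded from fingerprint

    @classmethod
    def create(cls, seed: int, config_path: str | Path | None = None,
               upset: str | None = None, duration_days: float = 40.0) -> "RunManifest":
        hashes = {}
        if config_path is not None:
            hashes[str(config_path)] = _sha256(config_path)
        return cls(
            seed=seed,
            config_path=None if config_path is None else str(config_path),
            upset=upset,
            duration_days=duration_days,
            input_sha256=hashes,
            created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def fingerprint(self) -> str:
        stable = {
            "seed": self.seed,
            "config_path": self.config_path,
            "upset": self.upset,
            "duration_days": self.duration_days,
            "package_version": self.package_version,
            "input_sha256": self.input_sha256,
        }
        return hashlib.sha256(json.dumps(stable, sort_keys=True).encode()).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "config_path": self.config_path,
            "upset": self.upset,
            "duration_days": self.duration_days,
            "package_version": self.package_version,
            "input_sha256": self.input_sha256,
            "fingerprint": self.fingerprint(),
        }
        with atomic_write(path) as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(manifest: RunManifest, out_dir: str | Path,
                 config: PipelineConfig | None = None) -> Path:
    """Simulate, observe, quantify and balance; write all artifacts to
    ``out_dir``.  Returns the report path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = load_config(manifest.config_path) if manifest.config_path else default_config()
    tag = f"manifest {manifest.fingerprint()}"
    log.info("run started (%s) at %s", tag, manifest.created)

    scenario = default_scenario(config.reactor, duration_days=manifest.duration_days)
    if manifest.upset:
        scenario = make_upset_scenario(scenario, manifest.upset)
    result = simulate_scenario(scenario, seed=manifest.seed)
    log.info("simulated %.0f days (%s)", manifest.duration_days, tag)

    obs = observe(result, config.noise, seed=manifest.seed, assays=config.assays)
    cells = quantify_plate(obs.plate, obs.curves, config.assays, obs.extraction)

    composition = cells.copy()
    fractions = []
    for day, group in cells.groupby("day"):
        comp = community_composition(dict(zip(group["species"], group["cells_per_ml"])))
        fractions.append(group["species"].map(comp.fractions))
    composition["fraction"] = pd.concat(fractions).reindex(composition.index)
    write_frame_csv(composition, out_dir / "composition.csv", header_comment=tag)

    final = cells[cells["day"] == cells["day"].max()]
    counts = dict(zip(final["species"], final["cells_per_ml"]))
    state = result.to_state()
    report = build_report(
        state,
        config.reactor,
        counts,
        splits=config.splits,
        calibration=config.calibration,
        digestible=config.digestible,
        energy_weights=config.energy_weights or None,
    )
    report_path = out_dir / "report.csv"
    with atomic_write(report_path) as fh:
        fh.write(f"# {tag}\n")
        report.to_frame().to_csv(fh)
    write_state_csv(config.reactor, state, out_dir / "steadystate.csv")
    manifest.write(out_dir / "manifest.json")
    log.info("report written to %s (%s)", report_path, tag)
    return report_path
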