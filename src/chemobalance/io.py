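"""CSV dialects and atomic file writing.

All tables are UTF-8, dot-decimal CSV with a mandatory header row; numeric
columns carry their units in the header name.  Writes go through a temp file
and ``os.replace`` so readers never see a partial file.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from . import compounds
from .chemostat import ChemostatState, ReactorConfig

__all__ = [
    "atomic_write",
    "write_state_csv",
    "read_state_csv",
    "write_frame_csv",
    "read_plate_csv",
    "read_standard_series_csv",
]

STATE_COLUMNS = ["compound", "phase", "feed_mM", "residual_mM"]
PLATE_COLUMNS = ["sample", "day", "species", "cq", "bio_rep", "tech_rep"]


@contextmanager
def atomic_write(path: str | Path, mode: str = "w") -> Iterator:
    """Write to a sibling temp file, then atomically replace ``path``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode, newline="") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def write_frame_csv(frame: pd.DataFrame, path: str | Path, *, index: bool = False,
                    header_comment: str | None = None) -> None:
    with atomic_write(path) as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=index)


def write_state_csv(config: ReactorConfig, state: ChemostatState, path: str | Path) -> None:
    """Steady-state table: compound, phase (liquid|gas), feed_mM, residual_mM."""
    names = sorted(set(config.feed_mM) | set(state.residual_mM))
    rows = []
    for name in names:
        try:
            phase = "gas" if compounds.get(name).role == "gas" else "liquid"
        except KeyError:
            phase = "liquid"
        rows.append(
            {
                "compound": name,
                "phase": phase,
                "feed_mM": config.feed_mM.get(name, 0.0),
                "residual_mM": state.residual_mM.get(name, 0.0),
            }
        )
    write_frame_csv(pd.DataFrame(rows, columns=STATE_COLUMNS), path)


def read_state_csv(path: str | Path) -> tuple[dict[str, float], dict[str, float]]:
    """Read a steady-state table; returns (feed_mM, residual_mM) mappings."""
    frame = pd.read_csv(path, comment="#")
    missing = set(STATE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"state table missing columns: {sorted(missing)}")
    feed = dict(zip(frame["compound"], frame["feed_mM"].astype(float)))
    residual = dict(zip(frame["compound"], frame["residual_mM"].astype(float)))
    return feed, residual


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    missing = set(PLATE_COLUMNS) - {"sample"} - set(frame.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    return frame


def read_standard_series_csv(path: str | Path) -> Mapping[str, pd.DataFrame]:
    """Standard-curve dilution series: columns species, copies, cq."""
    frame = pd.read_csv(path, comment="#")
    missing = {"species", "copies", "cq"} - set(frame.columns)
    if missing:
        raise ValueError(f"standard series missing columns: {sorted(missing)}")
    return {species: group for species, group in frame.groupby("species")}
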