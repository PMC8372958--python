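"""Persisted store of fitted mixture models used to warm-start new fits.

Models are saved as versioned JSON records under
``<root>/<cell_type>/<stage>/NNNNNN.json``; the insertion counter in the
filename gives a stable newest-first ordering that survives process
restarts.  Capacity per (cell_type, stage) is capped (oldest evicted);
the cap is configurable and can be disabled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .errors import CytogateError, InvalidInputError
from .gmm import MixtureModel

_ENTRY_RE = re.compile(r"^(\d{6})\.json$")

MEMORY_DIR_NAME = "flow cytometry analysis memory"


@dataclass
class AnalysisMemory:
    """Directory-backed model store keyed by cell type and pipeline stage."""

    root: Path
    capacity: int | None = 100

    def __post_init__(self) -> None:
        self.root = Path(self.root)

    def _slot(self, cell_type: str, stage: str) -> Path:
        for key in (cell_type, stage):
            if not key or "/" in key or key.startswith("."):
                raise InvalidInputError(f"invalid memory key {key!r}")
        return self.root / cell_type / stage

    def _entries(self, cell_type: str, stage: str) -> list[Path]:
        slot = self._slot(cell_type, stage)
        if not slot.is_dir():
            return []
        found = []
        for p in slot.iterdir():
            m = _ENTRY_RE.match(p.name)
            if m:
                found.append((int(m.group(1)), p))
        return [p for _, p in sorted(found)]

    def append(self, model: MixtureModel, cell_type: str, stage: str) -> Path:
        """Store a fitted model; evicts the oldest entry past capacity."""
        if not model.converged:
            raise InvalidInputError("only converged models are stored")
        slot = self._slot(cell_type, stage)
        try:
            slot.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise CytogateError(f"cannot create memory directory {slot}: {exc}")
        entries = self._entries(cell_type, stage)
        next_id = 0
        if entries:
            next_id = int(_ENTRY_RE.match(entries[-1].name).group(1)) + 1
        path = slot / f"{next_id:06d}.json"
        model.save(path)
        if self.capacity is not None:
            entries = self._entries(cell_type, stage)
            while len(entries) > self.capacity:
                entries.pop(0).unlink()
        return path

    def retrieve(self, cell_type: str, stage: str, m: int) -> list[MixtureModel]:
        """The ``m`` most recent models for this key, newest first."""
        if m <= 0:
            return []
        entries = self._entries(cell_type, stage)
        return [MixtureModel.load(p) for p in reversed(entries[-m:])]


def default_memory_root(data_directory: str | Path) -> Path:
    """The analysis-memory directory lives one level above the batch
    directory, shared across experiments."""
    return Path(data_directory).resolve().parent / MEMORY_DIR_NAME
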