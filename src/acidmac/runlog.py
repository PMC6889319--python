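"""Append-only CSV event logging for simulation runs."""

from __future__ import annotations

import csv
from pathlib import Path

from .errors import ParameterError


def write_run_log(events: list, path, flush_every: int = 100) -> None:
    """Append event rows (dicts with identical keys) to a CSV log.

    The header is written once, when the file is created or empty;
    reopening an existing log never duplicates it.  Rows are flushed every
    ``flush_every`` events.
    """
    p = Path(path)
    try:
        new_file = not p.exists() or p.stat().st_size == 0
        with p.open("a", newline="") as fh:
            if events:
                fieldnames = list(events[0].keys())
            elif new_file:
                fieldnames = ["time", "event", "site", "value"]
            else:
                return
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            if new_file:
                writer.writeheader()
            for i, row in enumerate(events, 1):
                writer.writerow(row)
                if i % flush_every == 0:
                    fh.flush()
    except OSError as exc:
        raise ParameterError(f"cannot write run log at {p}: {exc}") from exc
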