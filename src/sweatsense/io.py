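"""Plain-text serialization: signals, ground truth, layouts, result tables.

All formats are diffable tab-separated text with a one-line versioned schema
header, so simulated datasets and results can be inspected and re-read
losslessly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .device import DeviceLayout, GlandPlacement, SensorEvent, SensorSignal, build_layout

__all__ = [
    "write_signal",
    "read_signal",
    "write_ground_truth",
    "read_ground_truth",
    "write_layout",
    "read_layout",
    "write_results",
    "read_results",
]

SIGNAL_SCHEMA = "# sweatsense-signal v1\ttime_s\tvolume_nL"
TRUTH_SCHEMA = "# sweatsense-truth v1"
RESULTS_SCHEMA = "# sweatsense-results v1"


def write_signal(signal: SensorSignal, path: str | Path) -> None:
    """Write a sensed pulse train as (time_s, volume_nL) TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{SIGNAL_SCHEMA}\n")
        fh.write(f"# t_cycle_s\t{signal.t_cycle}\n")
        fh.write("time_s\tvolume_nL\n")
        for ev in signal.events:
            fh.write(f"{ev.time:.9g}\t{ev.volume:.9g}\n")


def read_signal(path: str | Path) -> SensorSignal:
    path = Path(path)
    t_cycle = None
    events: list[SensorEvent] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("time_s"):
                continue
            if line.startswith("#"):
                if "t_cycle_s" in line:
                    t_cycle = float(line.split("\t")[1])
                continue
            parts = line.split("\t")
            try:
                events.append(SensorEvent(time=float(parts[0]), volume=float(parts[1])))
            except (IndexError, ValueError) as err:
                raise ValueError(f"{path}:{lineno}: malformed signal line {line!r}") from err
    if t_cycle is None:
        raise ValueError(f"{path}: missing t_cycle_s header")
    return SensorSignal(events=tuple(events), t_cycle=t_cycle)


def write_ground_truth(
    placement: GlandPlacement, release_frame: pd.DataFrame, path: str | Path
) -> None:
    """Sidecar with gland placements and release times (evaluation only).

    ``release_frame`` is the (gland_id, cycle_index, time_s, volume_nL) table
    from :func:`sweatsense.sweatgen.events_to_frame`.
    """
    path = Path(path)
    frame = release_frame.copy()
    frame["site_dtravel"] = frame["gland_id"].map(
        {g: placement.dtravel(g) for g in placement.sites}
    )
    with path.open("w") as fh:
        fh.write(f"{TRUTH_SCHEMA}\tn_glands\t{placement.n_glands}\n")
    frame.to_csv(path, sep="\t", index=False, mode="a")


def read_ground_truth(path: str | Path) -> tuple[int, pd.DataFrame]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    n_glands = int(header[-1])
    frame = pd.read_csv(path, sep="\t", skiprows=1)
    return n_glands, frame


def write_layout(layout: DeviceLayout, path: str | Path) -> None:
    spec = {
        "name": layout.name,
        "distinct_dtravel": list(layout.distinct_dtravel),
        "occurrences": layout.occurrences,
        "t_cycle": layout.t_cycle,
        "v_min": layout.v_min,
        "n_leads": layout.n_leads,
    }
    Path(path).write_text(yaml.safe_dump(spec, sort_keys=False))


def read_layout(path: str | Path) -> DeviceLayout:
    spec = yaml.safe_load(Path(path).read_text())
    return build_layout(
        spec["name"],
        t_cycle=spec["t_cycle"],
        v_min=spec.get("v_min", 0.2),
        n_leads=spec.get("n_leads", 5),
        distinct_dtravel=spec["distinct_dtravel"],
        occurrences=spec["occurrences"],
    )


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{RESULTS_SCHEMA}\n")
    table.to_csv(path, sep="\t", index=False, mode="a")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
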