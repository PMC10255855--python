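"""End-to-end composition: simulate -> extract -> triage -> survive -> record.

:func:`run_pipeline` takes a :class:`PipelineConfig` (buildable from YAML),
renders each soldier's scenario, extracts windowed vital snapshots, runs
the triage cascade with the trained chance-of-survival function, appends
everything to per-casualty TCCC cards and emits decision *events* only when
the triage color changes — the downstream link carries changes, not every
evaluation.  All randomness flows from explicit seeds, so a rerun with the
same config reproduces byte-identical JSONL outputs.

:func:`render_board` is the medical-board view: one row per soldier with
the latest color, survival chance, reliability and data-freshness stamp,
ordered by evacuation priority (standard or reverse triage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from fieldtriage.signals import CalibrationRecord, snapshot_from_signals
from fieldtriage.simulate import GeneratedStream, ScenarioSpec, generate_scenario
from fieldtriage.survival import (
    SurvivalModel,
    generate_case_grid,
    label_grid,
    train_survival_model,
)
from fieldtriage.telemetry import TcccCard, update_tccc
from fieldtriage.triage import (
    ReferenceProfile,
    TriageColor,
    TriageDecision,
    VitalSnapshot,
    evacuation_order,
    triage,
)

__all__ = ["SoldierConfig", "PipelineConfig", "PipelineResult", "run_pipeline", "render_board"]


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the field."""


@dataclass(frozen=True)
class SoldierConfig:
    soldier_id: str
    scenario: ScenarioSpec
    profile: ReferenceProfile
    calibration: CalibrationRecord
    sex: str | None = None
    birth_date: str | None = None
    weight_kg: float | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; all seeds explicit."""

    soldiers: tuple[SoldierConfig, ...]
    window_s: float = 10.0
    period_s: float = 10.0
    model_seed: int = 42
    mode: str = "standard"

    def __post_init__(self) -> None:
        if not self.soldiers:
            raise ConfigError("soldiers: at least one soldier required")
        if self.window_s <= 0:
            raise ConfigError("window_s: must be > 0")
        if self.period_s <= 0:
            raise ConfigError("period_s: must be > 0")
        if self.mode not in ("standard", "reverse"):
            raise ConfigError(f"mode: unknown value {self.mode!r}")
        ids = [s.soldier_id for s in self.soldiers]
        if len(set(ids)) != len(ids):
            raise ConfigError("soldiers: duplicate soldier_id")
        for s in self.soldiers:
            if s.scenario.soldier_id != s.soldier_id:
                raise ConfigError(
                    f"scenario.soldier_id: {s.scenario.soldier_id!r} does not "
                    f"match soldier {s.soldier_id!r}"
                )

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PipelineConfig":
        try:
            soldiers = []
            for s in doc["soldiers"]:
                sid = str(s["soldier_id"])
                scen = dict(s["scenario"])
                scen.setdefault("soldier_id", sid)
                profile_doc = s.get("profile", {"soldier_id": sid})
                profile_doc.setdefault("soldier_id", sid)
                cal_doc = s.get("calibration", {})
                cal_doc.setdefault("soldier_id", sid)
                soldiers.append(
                    SoldierConfig(
                        soldier_id=sid,
                        scenario=ScenarioSpec.from_dict(scen),
                        profile=ReferenceProfile.from_dict(profile_doc),
                        calibration=CalibrationRecord(**cal_doc),
                        sex=s.get("sex"),
                        birth_date=s.get("birth_date"),
                        weight_kg=s.get("weight_kg"),
                    )
                )
        except KeyError as e:
            raise ConfigError(f"missing required field {e.args[0]!r}") from None
        return cls(
            soldiers=tuple(soldiers),
            window_s=float(doc.get("window_s", 10.0)),
            period_s=float(doc.get("period_s", 10.0)),
            model_seed=int(doc.get("model_seed", 42)),
            mode=str(doc.get("mode", "standard")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    streams: dict[str, GeneratedStream]
    snapshots: dict[str, list[VitalSnapshot]]
    decisions: dict[str, list[TriageDecision]]  # every evaluation
    events: list[TriageDecision]  # color changes only
    cards: dict[str, TcccCard]
    board: str

    def latest_decisions(self) -> list[TriageDecision]:
        return [ds[-1] for ds in self.decisions.values() if ds]


def _iso(ms: float) -> str:
    return (
        datetime.fromtimestamp(ms / 1000.0, tz=timezone.utc)
        .isoformat(timespec="milliseconds")
        .replace("+00:00", "Z")
    )


def extract_snapshots(
    stream: GeneratedStream,
    cal: CalibrationRecord,
    window_s: float = 10.0,
    period_s: float = 10.0,
) -> list[VitalSnapshot]:
    """Windowed extraction over a whole stream, one snapshot per period."""
    t0 = stream.spec.start_time_ms
    t_end = t0 + stream.spec.duration_s * 1000.0
    out = []
    t = t0 + window_s * 1000.0
    while t <= t_end:
        snap = snapshot_from_signals(
            stream.frames, cal, (t - window_s * 1000.0, t),
            soldier_id=stream.spec.soldier_id,
        )
        out.append(snap)
        t += period_s * 1000.0
    return out


def run_pipeline(
    config: PipelineConfig,
    model: SurvivalModel | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full chain for every configured soldier.

    A survival model is trained from the default triage-labeled case grid
    (seeded by ``config.model_seed``) unless one is supplied.  When
    ``out_dir`` is given, decisions events, snapshots and TCCC cards are
    written as JSONL/JSON with ISO-8601 timestamps.
    """
    if model is None:
        grid = generate_case_grid()
        labels = label_grid(grid, ReferenceProfile.default())
        model = train_survival_model(grid, labels, seed=config.model_seed)

    streams: dict[str, GeneratedStream] = {}
    snapshots: dict[str, list[VitalSnapshot]] = {}
    decisions: dict[str, list[TriageDecision]] = {}
    events: list[TriageDecision] = []
    cards: dict[str, TcccCard] = {}

    for s in config.soldiers:
        stream = generate_scenario(s.scenario)
        streams[s.soldier_id] = stream
        snaps = extract_snapshots(stream, s.calibration, config.window_s, config.period_s)
        snapshots[s.soldier_id] = snaps
        card = TcccCard(
            casualty_id=s.soldier_id, sex=s.sex, birth_date=s.birth_date,
            weight_kg=s.weight_kg,
        )
        ds: list[TriageDecision] = []
        last_color: TriageColor | None = None
        for snap in snaps:
            card = update_tccc(card, snap)
            def survival_fn(sn, _m=model):
                from fieldtriage.survival import survival_chance
                return survival_chance(_m, sn)
            decision = triage(snap, s.profile, survival_fn=survival_fn)
            ds.append(decision)
            if decision.color is not last_color:
                events.append(decision)
                card = update_tccc(card, decision)
                last_color = decision.color
        decisions[s.soldier_id] = ds
        cards[s.soldier_id] = card

    latest = [ds[-1] for ds in decisions.values() if ds]
    board = render_board(latest, mode=config.mode)

    result = PipelineResult(
        streams=streams, snapshots=snapshots, decisions=decisions,
        events=events, cards=cards, board=board,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    from fieldtriage.telemetry import export_tccc, snapshot_to_payload

    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "decisions.jsonl", "w") as fh:
        for d in sorted(result.events, key=lambda d: (d.timestamp, d.soldier_id)):
            ev = d.to_event()
            ev["timestamp"] = _iso(d.timestamp)
            fh.write(json.dumps(ev, sort_keys=True) + "\n")
    with open(out_dir / "snapshots.jsonl", "w") as fh:
        for sid in sorted(result.snapshots):
            for snap in result.snapshots[sid]:
                fh.write(snapshot_to_payload(snap).decode() + "\n")
    for sid, card in sorted(result.cards.items()):
        (out_dir / f"tccc_{sid}.json").write_text(
            json.dumps(export_tccc(card), indent=2, sort_keys=True)
        )
    (out_dir / "board.txt").write_text(result.board)


_BOARD_COLUMNS = ("soldier_id", "color", "survival_chance", "reliability", "last_update")


def render_board(
    decisions: Sequence[TriageDecision],
    mode: str = "standard",
    fmt: str = "text",
) -> str:
    """Tabular medical board: latest decision per soldier, priority order.

    ``fmt`` is "text" (aligned columns) or "csv".  Row order always equals
    :func:`~fieldtriage.triage.evacuation_order`.
    """
    ordered = evacuation_order(list(decisions), mode=mode)
    rows = []
    for d in ordered:
        rows.append(
            (
                d.soldier_id,
                d.color.value + ("*" if d.needs_confirmation else ""),
                "" if d.survival_chance is None else f"{d.survival_chance}",
                "" if d.reliability is None else f"{d.reliability}",
                _iso(d.timestamp),
            )
        )
    if fmt == "csv":
        lines = [",".join(_BOARD_COLUMNS)]
        lines += [",".join(r) for r in rows]
        return "\n".join(lines) + "\n"
    if fmt != "text":
        raise ValueError(f"unknown board format {fmt!r}")
    widths = [
        max(len(c), *(len(r[i]) for r in rows)) if rows else len(c)
        for i, c in enumerate(_BOARD_COLUMNS)
    ]
    header = "  ".join(c.ljust(w) for c, w in zip(_BOARD_COLUMNS, widths))
    sep = "  ".join("-" * w for w in widths)
    body = [
        "  ".join(v.ljust(w) for v, w in zip(r, widths)) for r in rows
    ]
    return "\n".join([header, sep, *body]) + "\n"
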