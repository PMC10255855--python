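"""Run the whole chain for a three-soldier engagement and print the board.

Simulates one healthy soldier, one hemorrhaging casualty and one with a
respiratory failure, extracts vitals, triages every reporting period with
the trained survival function, and renders the medical board in both
standard and reverse (lightest-first) evacuation modes.
"""

from fieldtriage import PipelineConfig, run_pipeline
from fieldtriage.pipeline import SoldierConfig, render_board
from fieldtriage.signals import CalibrationRecord
from fieldtriage.simulate import ScenarioSpec, Segment
from fieldtriage.triage import ReferenceProfile


def soldier(sid, seed, segments):
    return SoldierConfig(
        soldier_id=sid,
        scenario=ScenarioSpec(soldier_id=sid, seed=seed, segments=segments),
        profile=ReferenceProfile.default(sid),
        calibration=CalibrationRecord(soldier_id=sid),
    )


config = PipelineConfig(
    soldiers=(
        soldier("alpha", 1, (Segment(duration_s=120.0),)),
        soldier("bravo", 2, (Segment(duration_s=30.0),
                             Segment(duration_s=90.0, state="hemorrhage"))),
        soldier("charlie", 3, (Segment(duration_s=30.0),
                               Segment(duration_s=90.0, state="respiratory_failure"))),
    ),
    window_s=10.0,
    period_s=10.0,
    model_seed=42,
)

result = run_pipeline(config)
print("decision events (color changes only):")
for e in result.events:
    print(f"  {e.timestamp/1000:>6.0f}s {e.soldier_id:<8} -> {e.color.value}")

print("\nstandard board (most urgent first):")
print(result.board)
print("reverse-triage board (lightest first):")
print(render_board(result.latest_decisions(), mode="reverse"))
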