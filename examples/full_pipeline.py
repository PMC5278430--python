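"""Run the full synthetic pipeline end to end into ./pipeline_out.

Simulates paired chamber recordings, estimates reverberation times and
absorption factors, renders and measures a wing image, runs the
statistical battery and the detection-distance comparison, and writes
per-stage CSVs plus a JSON run report with file hashes.
"""

from pathlib import Path

from echowing import Band, ChamberSpec
from echowing.pipeline import RunConfig, run_pipeline

config = RunConfig(
    out_dir=Path("pipeline_out"),
    chamber=ChamberSpec(V=0.008, S=0.28),
    bands=[Band.from_centre(20_000.0)],
    fs=150_000.0,       # reduced sampling keeps the demo fast
    n_pos_empty=4,
    n_pos_wings=4,
    seed=0,
)
report = run_pipeline(config)
for name, digest in report["outputs"].items():
    print(f"{name:20s} sha256:{digest}")
print("Outputs are deterministic: rerunning with the same seed")
print("reproduces identical hashes.")
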