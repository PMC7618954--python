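"""Plain-text output formats for simulation results.

Rasters are two-column TSV (time_s, neuron_id) with 0-based ids in the
documented population order: excitatory neurons first, then inhibitory,
then Poisson inputs.  Rate tables are tidy CSV (assembly x time bin), and
run manifests are JSON files capturing every resolved parameter.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import ProtocolResult, StageRecording


def write_raster(stage: StageRecording, path) -> None:
    if stage.raster_t is None:
        raise ValueError("stage was recorded without a raster")
    df = pd.DataFrame({"time_s": stage.raster_t,
                       "neuron_id": stage.raster_id})
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_rate_table(result: ProtocolResult, path) -> None:
    """Assembly-by-time-bin rate table over baseline and stimulus."""
    rows = []
    for stage_name in ("baseline", "stimulus"):
        stage = result.stages[stage_name]
        series = stage.assembly_rate_series(result.members_E)
        for a in range(series.shape[0]):
            for b in range(series.shape[1]):
                rows.append({"stage": stage_name, "assembly": a + 1,
                             "time_s": (b + 0.5) * stage.bin_s,
                             "rate_hz": series[a, b]})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.4f")


def write_manifest(result: ProtocolResult, path) -> None:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v)
                    for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    manifest = {
        "condition": result.condition,
        "seed": result.seed,
        "config": clean(result.config),
        "layout": clean(result.layout),
        "condition_spec": clean(result.spec) if result.spec else None,
        "stages": {name: {"duration_s": st.duration_s, "bin_s": st.bin_s}
                   for name, st in result.stages.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
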