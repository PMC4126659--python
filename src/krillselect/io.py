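"""CSV schemas shared by the analysis stages and the CLI."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mesh_geometry import MeshDigitization
from .selectivity import CatchData

MORPHOMETRICS_COLUMNS = ["id", "length_mm", "cs", "b_mm", "h_mm"]
BOUNDARY_COLUMNS = ["id", "cs", "point_index", "x_mm", "y_mm"]
CATCH_COLUMNS = ["haul_id", "length_mm", "n_test", "n_control"]
MESH_COLUMNS = ["mesh_id", "point_index", "x_mm", "y_mm"]


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} CSV is missing columns {missing}")


def read_morphometrics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, MORPHOMETRICS_COLUMNS, "morphometrics")
    return df


def read_catch(path) -> CatchData:
    df = pd.read_csv(path)
    _require(df, CATCH_COLUMNS, "catch")
    frame = df.rename(
        columns={"haul_id": "haul", "length_mm": "length", "n_test": "nt", "n_control": "nc"}
    )
    return CatchData(frame[["haul", "length", "nt", "nc"]])


def write_catch(data: CatchData, path) -> None:
    out = data.frame.rename(
        columns={"haul": "haul_id", "length": "length_mm", "nt": "n_test", "nc": "n_control"}
    )
    out.to_csv(path, index=False)


def read_mesh_points(path) -> list[MeshDigitization]:
    df = pd.read_csv(path)
    _require(df, MESH_COLUMNS, "mesh digitisation")
    out = []
    for mesh_id, g in df.groupby("mesh_id"):
        g = g.sort_values("point_index")
        out.append(
            MeshDigitization(np.column_stack([g["x_mm"], g["y_mm"]]), mesh_id=mesh_id)
        )
    return out
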