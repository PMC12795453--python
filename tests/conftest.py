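"""Shared fixtures: tiny hand-written VAERS triplets and a small generated
population with known ground truth."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest

from pvsignal import synthetic

DATA_COLS = ["VAERS_ID", "RECVDATE", "AGE_YRS", "SEX", "DIED", "L_THREAT",
             "HOSPITAL", "X_STAY", "DISABLE", "BIRTH_DEFECT", "NUMDAYS",
             "VAX_DATE", "ONSET_DATE"]
SYM_COLS = ["VAERS_ID"] + [f"SYMPTOM{i}" for i in range(1, 6)] + \
           [f"SYMPTOMVERSION{i}" for i in range(1, 6)]
VAX_COLS = ["VAERS_ID", "VAX_TYPE", "VAX_NAME"]


def data_row(vaers_id: str, **kw) -> dict:
    row = {c: "" for c in DATA_COLS}
    row["VAERS_ID"] = vaers_id
    row["RECVDATE"] = kw.pop("RECVDATE", "06/15/2015")
    row.update(kw)
    return row


def sym_row(vaers_id: str, *pts: str) -> dict:
    row = {c: "" for c in SYM_COLS}
    row["VAERS_ID"] = vaers_id
    for i, pt in enumerate(pts, start=1):
        row[f"SYMPTOM{i}"] = pt
        row[f"SYMPTOMVERSION{i}"] = "27.0"
    return row


def vax_row(vaers_id: str, vax_name: str = "SYNFLORIX", vax_type: str = "PNC10") -> dict:
    return {"VAERS_ID": vaers_id, "VAX_TYPE": vax_type, "VAX_NAME": vax_name}


def write_triplet(directory: Path, data: list[dict], symptoms: list[dict],
                  vax: list[dict]) -> dict[str, Path]:
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "data": directory / "VAERSDATA.csv",
        "symptoms": directory / "VAERSSYMPTOMS.csv",
        "vax": directory / "VAERSVAX.csv",
    }
    pd.DataFrame(data, columns=DATA_COLS).to_csv(paths["data"], index=False)
    pd.DataFrame(symptoms, columns=SYM_COLS).to_csv(paths["symptoms"], index=False)
    pd.DataFrame(vax, columns=VAX_COLS).to_csv(paths["vax"], index=False)
    return paths


@pytest.fixture(scope="session")
def small_population() -> synthetic.GeneratedData:
    """A 1,900-report two-cohort population with default calibration."""
    cfg = synthetic.GeneratorConfig(seed=7, n_reports={"SYNFLORIX": 400, "OTHER": 1500})
    return synthetic.generate(cfg)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory, small_population) -> Path:
    d = tmp_path_factory.mktemp("fixture")
    synthetic.write_fixture(small_population, d)
    return d
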