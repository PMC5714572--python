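"""Packaged reference tables and the comparison harness.

The published characterization of the YAS glass seed prints all of its
reference data as tables (nuclide properties, activation products, glass
composition, transverse-axis dose rates per code, reference dose rates,
radial dose function, anisotropy function, quintic-fit coefficients). Those
tables are shipped here as plain CSV fixtures with a YAML sidecar declaring
units and provenance, and exposed through :func:`load_reference_table`.

:func:`compare_to_reference` is the generic per-cell comparison report used
by the consistency checks and the CLI ``compare`` subcommand.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

_TABLE_FILES = {
    "table1_nuclides": "table1_nuclides.csv",
    "table2_activation": "table2_activation.csv",
    "table3_composition": "table3_composition.csv",
    "table4_radial_dose_rate": "table4_radial_dose_rate.csv",
    "table5_reference_dose_rate": "table5_reference_dose_rate.csv",
    "table6_gL": "table6_gL.csv",
    "table7_F": "table7_F.csv",
    "eq1_coefficients": "eq1_coefficients.csv",
    "element_data": "element_data.csv",
}


@dataclass(frozen=True)
class ReferenceTable:
    name: str
    data: pd.DataFrame
    units: dict
    provenance: str


def _data_path(fname: str):
    return resources.files("betaseed.data").joinpath(fname)


def load_reference_table(name: str) -> ReferenceTable:
    """Load one of the packaged tables by name.

    Blank cells (points inside/behind the physical seed in the anisotropy
    table) come back as NaN, never imputed.
    """
    if name not in _TABLE_FILES:
        raise KeyError(
            f"unknown reference table {name!r}; available: "
            + ", ".join(sorted(_TABLE_FILES))
        )
    with _data_path(_TABLE_FILES[name]).open() as fh:
        df = pd.read_csv(fh)
    with _data_path("units.yaml").open() as fh:
        meta = yaml.safe_load(fh).get(name, {})
    return ReferenceTable(
        name=name,
        data=df,
        units=meta.get("units", {}),
        provenance=meta.get("provenance", ""),
    )


def anisotropy_table() -> tuple[pd.DataFrame, pd.Series]:
    """The packaged F(r, theta) grid and phi_an(r) row.

    Returns (F, phi_an): F indexed by theta in degrees with radius-in-mm
    float columns; phi_an indexed by radius.
    """
    raw = load_reference_table("table7_F").data
    radii = [float(c) for c in raw.columns[1:]]
    phi_row = raw[raw["theta_deg"] == "phi_an"]
    F = raw[raw["theta_deg"] != "phi_an"].copy()
    F.index = F["theta_deg"].astype(float)
    F = F.drop(columns="theta_deg")
    F.columns = radii
    F.index.name = "theta_deg"
    phi_an = pd.Series(
        phi_row.iloc[0, 1:].astype(float).values, index=radii, name="phi_an"
    )
    return F, phi_an


def compare_to_reference(
    computed: pd.DataFrame | pd.Series,
    reference: pd.DataFrame | pd.Series,
    rel_tolerance: float | None = None,
    abs_tolerance: float | None = None,
) -> pd.DataFrame:
    """Per-cell comparison of a computed table against a reference.

    Tables must share index/columns exactly (misalignment raises, with the
    offending labels in the message). Returns a long-format report with
    absolute and relative deviations and, if a tolerance was given, a
    ``pass`` column; the report's ``attrs['all_pass']`` summarizes it.
    """
    comp = computed.to_frame() if isinstance(computed, pd.Series) else computed
    ref = reference.to_frame() if isinstance(reference, pd.Series) else reference
    if not comp.index.equals(ref.index) or not comp.columns.equals(ref.columns):
        raise ValueError(
            "misaligned tables: index diff "
            f"{list(comp.index.symmetric_difference(ref.index))}, column diff "
            f"{list(comp.columns.symmetric_difference(ref.columns))}"
        )
    rows = []
    for col in comp.columns:
        for idx in comp.index:
            c, r = comp.loc[idx, col], ref.loc[idx, col]
            if pd.isna(c) and pd.isna(r):
                continue
            dev = c - r
            rel = dev / r if r != 0 else np.inf * np.sign(dev) if dev else 0.0
            rows.append({"index": idx, "column": col, "computed": c,
                         "reference": r, "abs_dev": dev, "rel_dev": rel})
    report = pd.DataFrame(rows)
    checks = []
    if abs_tolerance is not None:
        checks.append(report["abs_dev"].abs() <= abs_tolerance)
    if rel_tolerance is not None:
        checks.append(report["rel_dev"].abs() <= rel_tolerance)
    if checks:
        ok = checks[0]
        for c in checks[1:]:
            ok &= c
        report["pass"] = ok
        report.attrs["all_pass"] = bool(ok.all())
    report.attrs["max_abs_dev"] = float(report["abs_dev"].abs().max())
    report.attrs["max_rel_dev"] = float(report["rel_dev"].abs().max())
    return report
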