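"""Datasets, long-format CSV input and report output.

The bundled fixture ``table1`` is the dose-response case study: six groups
A-F of log10-transformed measurements (A is the control; B-F receive
increasing drug concentrations; lower values mean the drug performs better),
with group sizes 8, 10, 10, 9, 10, 9. The alternate fixture
``table1_dprime`` substitutes the modified column D' — column D shifted by
+1.5 on the raw scale before the log transform — used to illustrate a
decision whose reproducibility accumulates over several outcome vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .npi import Sample

__all__ = ["Dataset", "read_long_csv", "load_fixture", "write_report"]

FIXTURES = ("table1", "table1_dprime")


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of dose groups."""

    name: str
    groups: list[Sample] = field(repr=False)
    provenance: str = ""

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.groups]

    @property
    def g(self) -> int:
        return len(self.groups)

    def __getitem__(self, label: str) -> Sample:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (group, value) frame, groups in declared order."""
        return pd.DataFrame(
            [(g.label, v) for g in self.groups for v in g.values],
            columns=["group", "value"],
        )


def _dataset_from_frame(df: pd.DataFrame, name: str, provenance: str = "") -> Dataset:
    groups = [
        Sample(str(label), sub["value"].to_numpy())
        for label, sub in df.groupby("group", sort=False)
    ]
    return Dataset(name=name, groups=groups, provenance=provenance)


def read_long_csv(path) -> Dataset:
    """Read a long-format delimited table with columns ``group,value``.

    Group order follows first appearance in the file; values within a group
    are sorted ascending (the Sample invariant).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"group", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df[pd.to_numeric(df["value"], errors="coerce").isna()]
    if len(bad):
        # +2: header line and 1-based numbering
        raise ValueError(f"{path}: non-numeric value at row {bad.index[0] + 2}")
    df["value"] = df["value"].astype(float)
    if df["group"].isna().any() or (df["group"].astype(str).str.len() == 0).any():
        raise ValueError(f"{path}: empty group label")
    return _dataset_from_frame(df, name=path.stem, provenance=f"read from {path}")


def load_fixture(name: str = "table1") -> Dataset:
    """Load a bundled dataset.

    ``table1`` returns groups A-F of the dose-response case study;
    ``table1_dprime`` returns the same study with column D' in place of D.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURES}")
    with resources.files("npirepro.data").joinpath("table1.csv").open("r") as fh:
        df = pd.read_csv(fh)
    df = df.copy()
    if name == "table1":
        df = df[df["group"] != "D'"]
        note = "bundled dose-response case study, groups A-F (log10 scale)"
    else:
        df = df[df["group"] != "D"]
        order = ["A", "B", "C", "D'", "E", "F"]
        df["group"] = pd.Categorical(df["group"], categories=order, ordered=True)
        df = df.sort_values(["group"], kind="stable")
        df["group"] = df["group"].astype(str)
        note = "bundled case study with D' (D shifted +1.5 on the raw scale) replacing D"
    return _dataset_from_frame(df, name=name, provenance=note)


def write_report(results, path, fmt: str = "json") -> Path:
    """Write an analysis report.

    ``results`` is any object with ``to_dict()`` (reproducibility results) or
    a DataFrame (simulation records / frequency tables). Formats: ``json``,
    ``csv`` (tabular results only) and ``text`` (the ``summary()`` string).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        payload = results.to_dict() if hasattr(results, "to_dict") else results
        if isinstance(payload, pd.DataFrame):
            payload = payload.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif fmt == "csv":
        if hasattr(results, "frequency_frame"):
            results.frequency_frame().to_csv(path, index=False)
        elif isinstance(results, pd.DataFrame):
            results.to_csv(path, index=False)
        else:
            raise ValueError("csv format requires tabular results")
    elif fmt == "text":
        path.write_text(results.summary() + "\n" if hasattr(results, "summary") else str(results))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
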