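"""Packaged, versioned copies of the curated summary tables.

Three small TSV fixtures with a JSON schema sidecar: the 27-record EVE
summary across three host genome assemblies (``table1``), the five RNA-seq
datasets bearing near-complete virus contigs (``table2``), and the per-sample
TPM values for the viral pol/gag CDS features against the Actin-5C
housekeeping gene (``table3``). They are canonical inputs: invariants are
validated on every load and a violation is a hard error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from ..eve_caller import EveRecord
from ..io_formats import parse_coordinate_string

__all__ = [
    "FixtureError",
    "Table1Fixture",
    "Table2Fixture",
    "Table3Fixture",
    "load_fixture",
    "table1_eve_records",
]


class FixtureError(RuntimeError):
    """A packaged fixture failed its load-time validation."""


def _data_path(name: str):
    return resources.files(__name__).joinpath("data", name)


def _schema() -> dict:
    with _data_path("schema.json").open() as handle:
        return json.load(handle)


@dataclass(frozen=True)
class Table1Fixture:
    records: pd.DataFrame
    schema: dict


@dataclass(frozen=True)
class Table2Fixture:
    records: pd.DataFrame
    schema: dict


@dataclass(frozen=True)
class Table3Fixture:
    values: pd.DataFrame  # features x samples, TPM
    schema: dict

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def housekeeping(self) -> str:
        return self.schema["housekeeping"]

    @property
    def larval_samples(self) -> list[str]:
        return list(self.schema["larval_samples"])


def load_fixture(name: str):
    """Load and validate one of the packaged fixtures (table1/table2/table3)."""
    schema = _schema()
    if name not in schema:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(schema)}")
    meta = schema[name]
    if name == "table1":
        df = pd.read_csv(_data_path("table1.tsv").open(), sep="\t", dtype={"bga": int})
        if len(df) != meta["n_records"]:
            raise FixtureError(f"table1 must have {meta['n_records']} records, found {len(df)}")
        bad = set(df["locus_label"]) - set(meta["locus_labels"])
        if bad:
            raise FixtureError(f"table1 has unknown locus labels: {sorted(bad)}")
        for coord in df["coordinates"]:
            parse_coordinate_string(coord)  # raises on dialect violations
        return Table1Fixture(records=df, schema=meta)
    if name == "table2":
        df = pd.read_csv(_data_path("table2.tsv").open(), sep="\t")
        if len(df) != meta["n_records"]:
            raise FixtureError(f"table2 must have {meta['n_records']} records, found {len(df)}")
        return Table2Fixture(records=df, schema=meta)
    if name == "table3":
        df = pd.read_csv(_data_path("table3.tsv").open(), sep="\t", index_col="feature")
        if list(df.index) != meta["features"] or list(df.columns) != meta["samples"]:
            raise FixtureError("table3 features/samples do not match the schema")
        sums = df.sum(axis=0)
        if not (sums == meta["column_sum"]).all():
            raise FixtureError(
                f"every table3 sample column must sum to {meta['column_sum']}, got {sums.to_dict()}"
            )
        return Table3Fixture(values=df.astype(float), schema=meta)
    raise AssertionError("unreachable")


def table1_eve_records(fixture: Table1Fixture | None = None) -> list[EveRecord]:
    """The table1 fixture as typed :class:`EveRecord` objects.

    The assembly field carries the printed assembly number as ``BGA<n>``.
    """
    fixture = fixture or load_fixture("table1")
    records = []
    for row in fixture.records.itertuples(index=False):
        records.append(
            EveRecord(
                name=row.eve_name,
                assembly=f"BGA{row.bga}",
                interval=parse_coordinate_string(row.coordinates),
                family=row.family,
                best_hit_subject=row.best_hit,
                best_hit_pct_identity=float(row.aa_pct),
                protein_class=row.protein_class,
                locus_label=row.locus_label,
            )
        )
    return records
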