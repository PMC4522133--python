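"""TSV readers/writers for the pipeline's external interfaces.

Genotype tables carry one row per patient: ``patient_id``, the 11 panel
variant columns with VCF-style calls (``0/0``, ``0/1``, ``1/1``, ``./.``)
and an integer ``copy_number``.  Concentration tables carry ``patient_id``
plus one value column per analyte (ng/ml; empty = not detected) and an
optional ``<analyte>_status`` column; when the status column is absent the
status is derived from the analyte's linearity range (a value reported
below the LOLR is taken as an estimated concentration, since the instrument
only reports sub-LOLR values at acceptable signal-to-noise).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .metabolites import ANALYTES, LinearityRange, Measurement, PatientPanel, Status
from .star_allele import AlleleTable, CopyNumberCall, VariantState

__all__ = [
    "MalformedRowError",
    "read_genotype_table",
    "parse_genotype_row",
    "read_concentration_table",
    "write_concentration_table",
    "write_tsv",
]


class MalformedRowError(ValueError):
    """A TSV row that cannot be parsed; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


def read_genotype_table(path: str | Path, defs: AlleleTable) -> pd.DataFrame:
    """Read and validate a genotype TSV against the panel definition."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("./.")
    required = {"patient_id", "copy_number", *defs.panel_variants}
    missing = required - set(df.columns)
    if missing:
        raise MalformedRowError(1, f"missing column(s): {sorted(missing)}")
    valid = {s.value for s in VariantState}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        for v in defs.panel_variants:
            if row[v] not in valid:
                raise MalformedRowError(line, f"bad call {row[v]!r} at {v}")
        try:
            int(row["copy_number"])
        except ValueError:
            raise MalformedRowError(
                line, f"bad copy number {row['copy_number']!r}"
            ) from None
    return df


def parse_genotype_row(
    row: Mapping[str, str], defs: AlleleTable
) -> tuple[dict[str, VariantState], CopyNumberCall]:
    calls = {v: VariantState(row[v]) for v in defs.panel_variants}
    return calls, CopyNumberCall(copies=int(row["copy_number"]))


def read_concentration_table(
    path: str | Path,
    linearity: Mapping[str, LinearityRange] | None = None,
) -> list[PatientPanel]:
    """Read a concentration TSV into patient panels.

    Uses ``<analyte>_status`` columns when present; otherwise derives status
    from ``linearity`` (required in that case).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "patient_id" not in df.columns:
        raise MalformedRowError(1, "missing patient_id column")
    missing = set(ANALYTES) - set(df.columns)
    if missing:
        raise MalformedRowError(1, f"missing analyte column(s): {sorted(missing)}")
    have_status = all(f"{a}_status" in df.columns for a in ANALYTES)
    if not have_status and linearity is None:
        raise ValueError(
            "status columns absent: a linearity-range config is required"
        )
    panels = []
    for idx, row in df.iterrows():
        line = idx + 2
        measurements: dict[str, Measurement] = {}
        for a in ANALYTES:
            raw = row[a]
            value = None if (pd.isna(raw) or str(raw).strip() == "") else float(raw)
            if have_status:
                status = Status(row[f"{a}_status"])
                if status is Status.NOT_DETECTED:
                    measurements[a] = Measurement(None, Status.NOT_DETECTED)
                elif value is None:
                    raise MalformedRowError(
                        line, f"{a}: status {status.value} without a value"
                    )
                else:
                    measurements[a] = Measurement(value, status)
            else:
                rng = linearity[a]  # type: ignore[index]
                if value is None:
                    measurements[a] = Measurement(None, Status.NOT_DETECTED)
                elif value < rng.lo:
                    # A reported sub-LOLR value implies acceptable S/N.
                    measurements[a] = Measurement(value, Status.ESTIMATED_BELOW_LOLR)
                else:
                    measurements[a] = Measurement(
                        value, Status.QUANTIFIED, extrapolated=value > rng.hi
                    )
        panels.append(
            PatientPanel(patient_id=str(row["patient_id"]), measurements=measurements)
        )
    return panels


def write_concentration_table(panels: Sequence[PatientPanel], path: str | Path) -> None:
    rows = []
    for p in panels:
        row: dict[str, str] = {"patient_id": p.patient_id}
        for a in ANALYTES:
            m = p[a]
            row[a] = "" if m.concentration is None else f"{m.concentration:.6g}"
            row[f"{a}_status"] = m.status.value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
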