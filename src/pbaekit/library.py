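"""Data model and I/O for a PBAE polymer library.

A poly-beta-amino-ester (PBAE) is coded by the diacrylate (a letter), the
amine (a number) and the optional end-capping agent (e1 = ethylene-diamine,
e2 = diethylene-triamine, or none for acrylate-terminated chains).  Each
library member carries a row of numeric descriptors: computed properties of
the amine, the acrylate and the repeat unit, plus experimentally measured
polymer properties (molecular weights, zeta potential, hydrodynamic size,
drug loading, diffusion coefficient through cartilage).

Descriptors span incompatible physical units (Da, mV, nm, unitless), so all
distance and latent-variable computations downstream operate on z-scored
columns; :func:`standardize` produces them and keeps the constants needed to
map back.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PolymerID",
    "DescriptorTable",
    "StandardizedTable",
    "ValidationReport",
    "load_descriptor_table",
    "load_schema",
    "write_descriptor_table",
    "standardize",
    "validate_library",
]

VALID_ENDCAPS = ("e1", "e2", "none")

_ID_RE = re.compile(r"^([A-Za-z]+)(\d+)(?:-(e1|e2|none))?$")


@dataclass(frozen=True, order=True)
class PolymerID:
    """Identity of one library member: acrylate letter, amine number, end-cap."""

    acrylate_code: str
    amine_code: int
    endcap_code: str = "none"

    def __post_init__(self) -> None:
        if not self.acrylate_code:
            raise ValueError("acrylate_code must be non-empty")
        if self.amine_code <= 0:
            raise ValueError("amine_code must be a positive integer")
        if self.endcap_code not in VALID_ENDCAPS:
            raise ValueError(
                f"endcap_code must be one of {VALID_ENDCAPS}, got {self.endcap_code!r}"
            )

    def __str__(self) -> str:
        base = f"{self.acrylate_code}{self.amine_code}"
        return base if self.endcap_code == "none" else f"{base}-{self.endcap_code}"

    @classmethod
    def parse(cls, text: str) -> "PolymerID":
        """Parse ``A5``, ``A5-e2`` or ``A5-none`` style labels."""
        m = _ID_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse polymer id {text!r}")
        acr, amine, endcap = m.groups()
        return cls(acr, int(amine), endcap or "none")


COLUMN_SOURCES = ("amine", "acrylate", "repeat_unit", "experimental")


@dataclass
class DescriptorTable:
    """Polymer × descriptor numeric matrix with per-column source tags."""

    polymer_ids: list[PolymerID]
    descriptor_names: list[str]
    values: np.ndarray  # (n_polymers, n_descriptors)
    column_meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.polymer_ids):
            raise ValueError(
                f"{len(self.polymer_ids)} polymer ids but {n} value rows"
            )
        if p != len(self.descriptor_names):
            raise ValueError(
                f"{len(self.descriptor_names)} descriptor names but {p} value columns"
            )
        if len(set(self.descriptor_names)) != p:
            dupes = {d for d in self.descriptor_names if self.descriptor_names.count(d) > 1}
            raise ValueError(f"duplicate descriptor names: {sorted(dupes)}")
        if len(set(self.polymer_ids)) != n:
            dupes = {str(i) for i in self.polymer_ids if self.polymer_ids.count(i) > 1}
            raise ValueError(f"duplicate polymer ids: {sorted(dupes)}")

    @property
    def n_polymers(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            columns=self.descriptor_names,
            index=[str(i) for i in self.polymer_ids],
        )
        df.index.name = "polymer_id"
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, column_meta: dict[str, str] | None = None
    ) -> "DescriptorTable":
        ids = [PolymerID.parse(str(i)) for i in df.index]
        return cls(ids, list(df.columns), df.to_numpy(dtype=float), column_meta or {})


def load_descriptor_table(path, schema: dict[str, str] | None = None) -> DescriptorTable:
    """Read a descriptor CSV (first column ``polymer_id``, rest numeric).

    ``schema`` optionally maps descriptor name -> source tag in
    ``{amine, acrylate, repeat_unit, experimental}``; unknown tags raise.
    Missing/NaN cells and duplicate polymer ids are validation errors that
    name the offending coordinates.
    """
    df = pd.read_csv(path, index_col=0)
    if df.index.name != "polymer_id":
        raise ValueError(
            f"first column must be named 'polymer_id', got {df.index.name!r}"
        )
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate polymer id(s): {dupes}")
    try:
        values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric descriptor value in {path}: {exc}") from exc
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        cells = [
            f"({df.index[i]}, {df.columns[j]})" for i, j in bad[:20]
        ]
        raise ValueError(f"missing/non-finite cells: {', '.join(cells)}")
    if schema:
        unknown = set(schema.values()) - set(COLUMN_SOURCES)
        if unknown:
            raise ValueError(f"unknown column source tags: {sorted(unknown)}")
    table = DescriptorTable.from_frame(df, dict(schema or {}))
    return table


def write_descriptor_table(table: DescriptorTable, path) -> None:
    table.to_frame().to_csv(path)


def load_schema(path) -> dict[str, str]:
    """Read a YAML/JSON schema file mapping descriptor name -> source tag.

    Entries may be plain tags (``amine``) or mappings with a ``source`` key
    (and e.g. a ``unit`` string, which is ignored here).
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("schema file must map descriptor names to source tags")
    schema = {
        name: (entry["source"] if isinstance(entry, dict) else str(entry))
        for name, entry in doc.items()
    }
    unknown = set(schema.values()) - set(COLUMN_SOURCES)
    if unknown:
        raise ValueError(f"unknown column source tags: {sorted(unknown)}")
    return schema


@dataclass
class StandardizedTable:
    """z-scored descriptor table with the constants to undo the scaling.

    Constant columns cannot be z-scored; they are excluded from ``z_values``
    and listed in ``excluded_constant``.
    """

    base: DescriptorTable
    column_means: np.ndarray
    column_sds: np.ndarray
    z_values: np.ndarray
    kept_names: list[str]
    excluded_constant: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.z_values,
            columns=self.kept_names,
            index=[str(i) for i in self.base.polymer_ids],
        )
        df.index.name = "polymer_id"
        return df


def standardize(table: DescriptorTable) -> StandardizedTable:
    """z-score every column (mean 0, sample SD 1, ddof=1).

    Columns with zero variance are excluded and flagged rather than divided
    by zero; the means/SDs of the kept columns are retained so model outputs
    can be mapped back to original units.
    """
    if table.n_polymers < 2:
        raise ValueError("standardization needs at least 2 rows")
    means = table.values.mean(axis=0)
    sds = table.values.std(axis=0, ddof=1)
    keep = sds > 0
    excluded = [n for n, k in zip(table.descriptor_names, keep) if not k]
    kept_names = [n for n, k in zip(table.descriptor_names, keep) if k]
    z = (table.values[:, keep] - means[keep]) / sds[keep]
    return StandardizedTable(
        base=table,
        column_means=means[keep],
        column_sds=sds[keep],
        z_values=z,
        kept_names=kept_names,
        excluded_constant=excluded,
    )


@dataclass
class ValidationReport:
    missing_cells: list[tuple[str, str]]
    constant_columns: list[str]
    correlated_pairs: list[tuple[str, str, float]]

    @property
    def ok(self) -> bool:
        return not (self.missing_cells or self.constant_columns or self.correlated_pairs)


def validate_library(
    table: DescriptorTable, correlation_threshold: float = 0.95
) -> ValidationReport:
    """Report-only data quality checks.

    Surfaces missing values, constant columns and descriptor pairs whose
    absolute Pearson correlation exceeds ``correlation_threshold`` — the
    multicollinearity that motivates latent-variable regression over OLS on
    these libraries.
    """
    vals = table.values
    missing = [
        (str(table.polymer_ids[i]), table.descriptor_names[j])
        for i, j in np.argwhere(~np.isfinite(vals))
    ]
    sds = np.nanstd(vals, axis=0, ddof=1)
    constant = [n for n, s in zip(table.descriptor_names, sds) if not s > 0]
    pairs: list[tuple[str, str, float]] = []
    varying = np.flatnonzero(sds > 0)
    if varying.size >= 2 and not missing:
        corr = np.corrcoef(vals[:, varying], rowvar=False)
        for a in range(len(varying)):
            for b in range(a + 1, len(varying)):
                r = corr[a, b]
                if abs(r) > correlation_threshold:
                    pairs.append(
                        (
                            table.descriptor_names[varying[a]],
                            table.descriptor_names[varying[b]],
                            float(r),
                        )
                    )
    return ValidationReport(missing, constant, pairs)
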