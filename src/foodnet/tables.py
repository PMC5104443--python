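"""Reading production / import / population tables and matrix round-trips.

Long-format input: one record per row, CSV or TSV, configurable column
names. Production and import tables share the layout
(country, product, year, tonnes); population tables are
(country, year, persons). Matrices are written as labeled dense TSV
(bit-exact round trip) with an optional MatrixMarket-style sparse
companion.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse as _sparse
from scipy.io import mmwrite

from foodnet.panel import BipartitePanel

logger = logging.getLogger(__name__)

DEFAULT_MIN_POP = 500_000

_DIALECT_COLUMNS = {
    "production": ("country", "product", "year", "tonnes"),
    "import": ("country", "product", "year", "tonnes"),
    "population": ("country", "year", "persons"),
}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_records(
    path: str | Path,
    dialect: str = "production",
    columns: dict[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a long-format record table and validate it.

    Parameters
    ----------
    path : file path
        CSV/TSV file with a header row.
    dialect : {"production", "import", "population"}
        Selects the expected columns: (country, product, year, tonnes)
        for production/import, (country, year, persons) for population.
    columns : mapping, optional
        Maps canonical names to the header names actually used in the
        file, e.g. ``{"country": "Area", "tonnes": "Value"}``.
    sep : str, optional
        Field delimiter; inferred from the extension when omitted
        (tab for .tsv/.tab/.txt, comma otherwise).

    Returns
    -------
    DataFrame with canonical column names and validated dtypes.

    Raises
    ------
    ValueError
        On a missing required column, an unparseable numeric field, a
        negative tonnage, or a non-positive population count. Messages
        name the offending file line (header is line 1).
    """
    path = Path(path)
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    canonical = _DIALECT_COLUMNS[dialect]
    colmap = {name: name for name in canonical}
    if columns:
        colmap.update({k: v for k, v in columns.items() if k in colmap})

    df = pd.read_csv(path, sep=sep or _sep_for(path), dtype=str, comment="#", skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]

    missing = [colmap[name] for name in canonical if colmap[name] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} for dialect {dialect!r}")

    out = pd.DataFrame({name: df[colmap[name]] for name in canonical})
    # first data row of the file is line 2
    out.index = df.index + 2

    for label_col in ("country", "product"):
        if label_col in out:
            out[label_col] = out[label_col].astype(str).str.strip()

    out["year"] = _to_numeric(out["year"], "year", path, integer=True)
    if dialect == "population":
        out["persons"] = _to_numeric(out["persons"], "persons", path)
        bad = out.index[out["persons"] <= 0]
        if len(bad):
            raise ValueError(f"{path}: non-positive persons at line {bad[0]}")
    else:
        out["tonnes"] = _to_numeric(out["tonnes"], "tonnes", path)
        bad = out.index[out["tonnes"] < 0]
        if len(bad):
            raise ValueError(f"{path}: negative tonnes at line {bad[0]}")
    return out.reset_index(drop=True)


def _to_numeric(col: pd.Series, name: str, path: Path, integer: bool = False) -> pd.Series:
    converted = pd.to_numeric(col, errors="coerce")
    bad = col.index[converted.isna()]
    if len(bad):
        raise ValueError(f"{path}: malformed {name} value {col[bad[0]]!r} at line {bad[0]}")
    return converted.astype(int) if integer else converted.astype(float)


def filter_countries(
    records: pd.DataFrame,
    population: pd.DataFrame,
    year: int,
    min_pop: int = DEFAULT_MIN_POP,
) -> pd.DataFrame:
    """Keep only records of countries whose population strictly exceeds
    ``min_pop`` in ``year``.

    Countries absent from the population table are dropped with a logged
    warning. Filtering is total (never raises) and idempotent.
    """
    pop_year = population[population["year"] == year]
    pop_by_country = pop_year.set_index("country")["persons"]

    present = records["country"].unique()
    unknown = sorted(set(present) - set(pop_by_country.index))
    if unknown:
        logger.warning(
            "dropping %d countries with no population record for %d: %s",
            len(unknown), year, ", ".join(unknown),
        )
    keep = pop_by_country[pop_by_country > min_pop].index
    out = records[records["country"].isin(keep)].reset_index(drop=True)
    if out.empty and not records.empty:
        logger.warning("no countries above population threshold %d in %d", min_pop, year)
    return out


def build_panel(
    records: pd.DataFrame,
    population: pd.DataFrame,
    year: int,
) -> BipartitePanel:
    """Construct the binary and per-capita weighted matrices for one year.

    Duplicate (country, product) rows are summed. ``M[c, p] = 1`` iff the
    summed tonnage is strictly positive; ``W[c, p] = tonnes / persons``.
    Countries/products whose rows/columns end up all-zero are retained and
    flagged in ``panel.meta``.

    Raises
    ------
    ValueError if a retained country has no population record for ``year``.
    """
    sub = records[records["year"] == year]
    countries = sorted(sub["country"].unique())
    products = sorted(sub["product"].unique())

    pop_year = population[population["year"] == year].set_index("country")["persons"]
    missing = [c for c in countries if c not in pop_year.index]
    if missing:
        raise ValueError(f"missing population for {missing} in year {year}")

    totals = sub.groupby(["country", "product"])["tonnes"].sum()
    tonnage = (
        totals.unstack(fill_value=0.0)
        .reindex(index=countries, columns=products, fill_value=0.0)
        .to_numpy(dtype=float)
    )
    persons = pop_year.reindex(countries).to_numpy(dtype=float)
    W = tonnage / persons[:, None]

    panel = BipartitePanel.from_weighted(int(year), countries, products, W)
    panel.meta["zero_countries"] = panel.zero_countries()
    panel.meta["zero_products"] = panel.zero_products()
    if panel.meta["zero_countries"] or panel.meta["zero_products"]:
        logger.warning(
            "panel %d has %d all-zero countries and %d all-zero products",
            year, len(panel.meta["zero_countries"]), len(panel.meta["zero_products"]),
        )
    return panel


# ---------------------------------------------------------------------------
# matrix writers / readers


def write_matrix(
    panel: BipartitePanel,
    path: str | Path,
    form: str = "weighted",
    sparse: bool = False,
    header: dict | None = None,
) -> None:
    """Write a panel matrix as a labeled dense TSV.

    The first column holds country labels, the header row product labels.
    Weighted values are written with ``repr`` so the dense file
    round-trips bit-exactly through :func:`read_matrix`. ``# key=value``
    comment lines (year plus any ``header`` entries) precede the table.

    With ``sparse=True`` a MatrixMarket coordinate file is written next
    to ``path`` (suffix ``.mtx``) along with ``<path>.labels.tsv``.
    """
    if form not in {"binary", "weighted"}:
        raise ValueError(f"form must be 'binary' or 'weighted', got {form!r}")
    path = Path(path)
    X = panel.M if form == "binary" else panel.W

    lines = [f"# year={panel.year}", f"# form={form}"]
    for key, value in (header or {}).items():
        lines.append(f"# {key}={value}")
    lines.append("\t".join(["country"] + list(panel.products)))
    fmt = (lambda v: str(int(v))) if form == "binary" else (lambda v: repr(float(v)))
    for label, row in zip(panel.countries, X):
        lines.append("\t".join([label] + [fmt(v) for v in row]))
    path.write_text("\n".join(lines) + "\n")

    if sparse:
        mmwrite(str(path.with_suffix(".mtx")), _sparse.coo_matrix(X))
        label_lines = ["side\tindex\tlabel"]
        label_lines += [f"country\t{i}\t{c}" for i, c in enumerate(panel.countries)]
        label_lines += [f"product\t{j}\t{p}" for j, p in enumerate(panel.products)]
        Path(str(path) + ".labels.tsv").write_text("\n".join(label_lines) + "\n")


def read_matrix(path: str | Path) -> BipartitePanel:
    """Read a dense labeled TSV written by :func:`write_matrix`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
        elif line.strip():
            rows.append(line)
    if not rows:
        raise ValueError(f"{path}: no table found")
    products = rows[0].split("\t")[1:]
    countries, values = [], []
    for row in rows[1:]:
        cells = row.split("\t")
        countries.append(cells[0])
        values.append([float(v) for v in cells[1:]])
    W = np.array(values, dtype=float) if values else np.empty((0, len(products)))
    year = int(meta.get("year", 0))
    panel = BipartitePanel.from_weighted(year, countries, products, W)
    panel.meta.update(meta)
    return panel
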