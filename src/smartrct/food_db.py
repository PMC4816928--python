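"""Barcode-keyed food composition database.

The database backs both modes of the trial app: intervention delivery
(nutrient content feeds the label engine) and data collection (scanned
barcodes are matched against it to build electronic shopping lists).
Products carry nutrient content per 100 g (foods) or 100 mL (beverages)
plus a serving size, mirroring how packaged-food composition tables are
distributed in Australia and New Zealand.

The database is static for a run: it is loaded once from CSV and never
mutated, so lookups are plain dictionary access and category sampling is
reproducible under a seeded generator.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ScanFormatError

#: Column order of the canonical CSV interchange format.
CSV_COLUMNS = [
    "barcode", "name", "category_id", "is_beverage", "serving_size",
    "energy_kj_100", "protein_g_100", "fat_g_100", "satfat_g_100",
    "carb_g_100", "sugars_g_100", "fibre_g_100", "sodium_mg_100", "fvnl_pct",
]

_REQUIRED_NUTRIENTS = [
    "energy_kj_100", "protein_g_100", "fat_g_100", "satfat_g_100",
    "carb_g_100", "sugars_g_100", "sodium_mg_100",
]


@dataclass(frozen=True)
class Product:
    """One packaged food or beverage, keyed by its EAN barcode.

    Nutrient amounts are per 100 g for foods and per 100 mL for
    beverages; ``is_beverage`` selects which label-scheme tables apply.
    ``fibre_g_100`` and ``fvnl_pct`` (fruit/vegetable/nut/legume content)
    are optional because many commercial composition records omit them.
    """

    barcode: str
    name: str
    category_id: str
    is_beverage: bool
    serving_size: float
    energy_kj_100: float
    protein_g_100: float
    fat_g_100: float
    satfat_g_100: float
    carb_g_100: float
    sugars_g_100: float
    sodium_mg_100: float
    fibre_g_100: Optional[float] = None
    fvnl_pct: Optional[float] = None

    def per_serving(self, nutrient: str) -> float:
        """Convert a per-100 g/mL nutrient amount to per serving."""
        value = getattr(self, nutrient)
        if value is None:
            raise ValueError(f"nutrient {nutrient!r} not recorded for {self.barcode}")
        return value * self.serving_size / 100.0


def validate_barcode(code: str) -> Optional[str]:
    """Return a rejection reason for a malformed barcode, else None."""
    if not code or not code.isdigit():
        return "barcode not a digit string"
    if len(code) not in (8, 13):
        return "barcode length not 8 or 13"
    return None


def ean_check_digit_ok(code: str) -> bool:
    """Verify the EAN-8/EAN-13 modulo-10 check digit.

    Digits are weighted 3,1,3,1,... starting from the digit adjacent to
    the check digit (rightmost first).
    """
    digits = [int(c) for c in code]
    body, check = digits[:-1], digits[-1]
    total = sum(d * (3 if i % 2 == 0 else 1) for i, d in enumerate(reversed(body)))
    return (10 - total % 10) % 10 == check


@dataclass
class ValidationReport:
    """Outcome of a database load: rejected rows and advisory warnings."""

    n_rows: int = 0
    n_loaded: int = 0
    rejected: list[dict] = field(default_factory=list)
    warnings: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.rejected

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class FoodDatabase:
    """Immutable barcode index over loaded products."""

    products: dict[str, Product]
    category_index: dict[str, list[str]]
    report: ValidationReport = field(default_factory=ValidationReport)

    def __len__(self) -> int:
        return len(self.products)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.products


def _parse_row(row: pd.Series, idx: int) -> tuple[Optional[Product], Optional[str]]:
    """Validate one CSV row; return (product, None) or (None, reason)."""
    code = str(row["barcode"]).strip()
    reason = validate_barcode(code)
    if reason:
        return None, reason

    def _num(col: str, required: bool) -> Optional[float]:
        raw = row.get(col)
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
            if required:
                raise ValueError(f"missing value for {col}")
            return None
        return float(raw)

    try:
        serving = _num("serving_size", required=True)
        nutrients = {c: _num(c, required=True) for c in _REQUIRED_NUTRIENTS}
        fibre = _num("fibre_g_100", required=False)
        fvnl = _num("fvnl_pct", required=False)
    except (ValueError, TypeError) as exc:
        return None, str(exc)

    if serving <= 0:
        return None, "serving_size must be > 0"
    for col, val in nutrients.items():
        if val < 0:
            return None, f"negative nutrient {col}"
    if fibre is not None and fibre < 0:
        return None, "negative nutrient fibre_g_100"
    if fvnl is not None and not (0 <= fvnl <= 100):
        return None, "fvnl_pct outside [0, 100]"

    is_bev = str(row["is_beverage"]).strip().lower() in ("1", "true", "yes", "y")
    product = Product(
        barcode=code,
        name=str(row["name"]),
        category_id=str(row["category_id"]),
        is_beverage=is_bev,
        serving_size=serving,
        fibre_g_100=fibre,
        fvnl_pct=fvnl,
        **nutrients,
    )
    return product, None


def load_database(path: str | Path) -> FoodDatabase:
    """Load and validate a food composition CSV.

    Every valid row becomes a :class:`Product`. Invalid rows are
    rejected (never fatal) and listed in the validation report with a
    reason; the first occurrence wins when two rows share a barcode.
    An EAN check-digit mismatch is reported as a warning only, since
    real composition databases contain nonconforming codes.

    Raises
    ------
    FormatError
        If a required column is missing from the header.
    """
    df = pd.read_csv(path, dtype={"barcode": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    report = ValidationReport(n_rows=len(df))
    products: dict[str, Product] = {}
    category_index: dict[str, list[str]] = defaultdict(list)

    for idx, row in df.iterrows():
        product, reason = _parse_row(row, idx)
        if product is None:
            report.rejected.append({"row": int(idx), "barcode": str(row.get("barcode", "")), "reason": reason})
            continue
        if product.barcode in products:
            report.rejected.append({
                "row": int(idx), "barcode": product.barcode,
                "reason": "duplicate barcode (first occurrence kept)",
            })
            continue
        if not ean_check_digit_ok(product.barcode):
            report.warnings.append({
                "row": int(idx), "barcode": product.barcode,
                "reason": "EAN check digit mismatch",
            })
        products[product.barcode] = product
        category_index[product.category_id].append(product.barcode)

    report.n_loaded = len(products)
    return FoodDatabase(products=products, category_index=dict(category_index), report=report)


def build_database(products: Iterable[Product]) -> FoodDatabase:
    """Assemble a database from in-memory products (first barcode wins)."""
    index: dict[str, Product] = {}
    cats: dict[str, list[str]] = defaultdict(list)
    report = ValidationReport()
    for p in products:
        report.n_rows += 1
        if p.barcode in index:
            report.rejected.append({"row": report.n_rows - 1, "barcode": p.barcode,
                                    "reason": "duplicate barcode (first occurrence kept)"})
            continue
        index[p.barcode] = p
        cats[p.category_id].append(p.barcode)
    report.n_loaded = len(index)
    return FoodDatabase(products=index, category_index=dict(cats), report=report)


def match_barcode(db: FoodDatabase, code: str) -> Optional[Product]:
    """Look up a scanned barcode.

    A miss returns ``None`` rather than raising: unrecognized products
    are a normal outcome that feeds the crowdsourcing workflow.

    Raises
    ------
    ScanFormatError
        If ``code`` contains non-digit characters.
    """
    if not code.isdigit():
        raise ScanFormatError(f"scanned code {code!r} is not a digit string")
    return db.products.get(code)


def related_products(db: FoodDatabase, product: Product, n: int,
                     rng: np.random.Generator) -> list[Product]:
    """Sample up to ``n`` other products from the same category.

    Shown under the nutrition label in intervention mode so participants
    can compare the scanned product against category peers. Sampling is
    without replacement, excludes the query product, and is reproducible
    under a fixed generator state.
    """
    pool = [b for b in db.category_index.get(product.category_id, []) if b != product.barcode]
    if not pool:
        return []
    k = min(n, len(pool))
    chosen = rng.choice(len(pool), size=k, replace=False)
    return [db.products[pool[i]] for i in chosen]
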