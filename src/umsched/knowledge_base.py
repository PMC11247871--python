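"""Drug knowledge base: products, ingredients, per-drug and pairwise
interval constraints, and drug-drug interaction (DDI) records.

The KB mirrors how label-derived dosing knowledge is organised in
interaction-aware scheduling systems:

* an MTCOD record ("medication time constraint, one drug") holds, per
  product, the doses per day, the minimum interval between successive
  doses (Min-ISD), the maximum interval (Max-ISD = 24 h / doses per day,
  floored to the 0.25 h grid), an optional symbolic meal constraint and
  optional absolute chronopharmacology windows;
* an MTCMD record ("medication time constraint, multi drug") holds a
  *directional* product pair with the minimum/maximum interval between the
  two drugs in a day (Min-ITD / Max-ITD) — (A, B) and (B, A) are distinct
  rows because the safe separation depends on administration order;
* DDI records pair two *ingredients* (unordered) with a severity class
  (major / moderate / minor / unknown).

Tabular I/O is CSV (UTF-8, header row) with a single-file JSON bundle
alternative; symbolic constraints are stored as DSL strings.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .constraint_dsl import (
    GRID,
    TimeConstraintExpr,
    TimeWindow,
    parse_time_expr,
    render_time_expr,
    snap,
)


class Severity(enum.Enum):
    MAJOR = "major"
    MODERATE = "moderate"
    MINOR = "minor"
    UNKNOWN = "unknown"

    @property
    def rank(self) -> int:
        return {"major": 3, "moderate": 2, "minor": 1, "unknown": 0}[self.value]


class ProductCategory(enum.Enum):
    WESTERN = "western"
    CHINESE_PATENT = "chinese_patent"


class Origin(enum.Enum):
    DOMESTIC = "domestic"
    IMPORTED = "imported"


class IngredientClass(enum.Enum):
    CHEMICAL = "chemical"
    TCM_EXTRACT = "tcm_extract"
    NATURAL_PRODUCT = "natural_product"


class DDISource(enum.Enum):
    A_SOURCE = "A"  # interaction checker database
    B_SOURCE = "B"  # product instructions


class KBValidationError(ValueError):
    """Raised on any KB invariant violation; message lists the offenders."""


@dataclass(frozen=True)
class Ingredient:
    ingredient_id: str
    name: str
    ingredient_class: IngredientClass


@dataclass(frozen=True)
class PharmaceuticalProduct:
    product_id: str
    name: str
    ingredients: tuple[str, ...]
    otc: bool = False
    category: ProductCategory = ProductCategory.WESTERN
    origin: Origin = Origin.DOMESTIC

    def __post_init__(self):
        if not self.ingredients:
            raise ValueError(f"product {self.product_id} has no ingredients")


def compute_max_isd(doses_per_day: int) -> float:
    """Max-ISD: 24 h divided by the daily dose count, floored to the grid.

    >>> compute_max_isd(2)
    12.0
    >>> compute_max_isd(7)
    3.25
    """
    if not isinstance(doses_per_day, int) or doses_per_day < 1:
        raise ValueError(f"doses_per_day must be a positive integer, got {doses_per_day!r}")
    return math.floor(24.0 / doses_per_day / GRID) * GRID


@dataclass(frozen=True)
class MTCODRecord:
    """Per-product dosing constraints."""

    product_id: str
    doses_per_day: int
    min_isd: float
    max_isd: float
    meal_constraint: TimeConstraintExpr | None = None
    chrono_windows: tuple[TimeWindow, ...] = ()
    prn: bool = False

    def __post_init__(self):
        if self.doses_per_day < 1:
            raise ValueError(f"{self.product_id}: doses_per_day must be >= 1")
        if not (0 < self.min_isd <= self.max_isd <= 24):
            raise ValueError(
                f"{self.product_id}: need 0 < min_isd <= max_isd <= 24, "
                f"got {self.min_isd}, {self.max_isd}"
            )
        if self.doses_per_day * self.min_isd > 24 + 1e-9:
            raise ValueError(f"{self.product_id}: doses_per_day * min_isd exceeds 24 h")


@dataclass(frozen=True)
class MTCMDRecord:
    """Directional interval constraint between two products."""

    first_product_id: str
    second_product_id: str
    min_itd: float
    max_itd: float

    def __post_init__(self):
        if not (0 <= self.min_itd <= self.max_itd <= 24):
            raise ValueError(
                f"MTCMD {self.first_product_id}->{self.second_product_id}: "
                f"need 0 <= min_itd <= max_itd <= 24, got {self.min_itd}, {self.max_itd}"
            )


@dataclass(frozen=True)
class DDIRecord:
    """Unordered ingredient pair with a severity class."""

    ingredient_a: str
    ingredient_b: str
    severity: Severity
    mechanism_note: str = ""
    source: DDISource = DDISource.A_SOURCE

    @property
    def canonical_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.ingredient_a, self.ingredient_b)))


def dedupe_ddi(records: Iterable[DDIRecord]) -> list[DDIRecord]:
    """One record per canonical unordered pair; the most severe wins.

    Idempotent; preserves first-seen pair order.
    """
    best: dict[tuple[str, str], DDIRecord] = {}
    for r in records:
        key = r.canonical_pair
        prev = best.get(key)
        if prev is None or r.severity.rank > prev.severity.rank:
            best[key] = r
    return list(best.values())


@dataclass
class KnowledgeBase:
    products: dict[str, PharmaceuticalProduct] = field(default_factory=dict)
    ingredients: dict[str, Ingredient] = field(default_factory=dict)
    mtcod: dict[str, MTCODRecord] = field(default_factory=dict)
    mtcmd: dict[tuple[str, str], MTCMDRecord] = field(default_factory=dict)
    ddi: list[DDIRecord] = field(default_factory=list)

    def validate(self) -> None:
        """Check every invariant; raise :class:`KBValidationError` listing all."""
        errors: list[str] = []
        for pid, p in self.products.items():
            if pid != p.product_id:
                errors.append(f"product key {pid} != record id {p.product_id}")
            for ing in p.ingredients:
                if ing not in self.ingredients:
                    errors.append(f"product {pid}: unknown ingredient {ing}")
        for pid in self.products:
            if pid not in self.mtcod:
                errors.append(f"product {pid}: missing MTCOD record")
        for pid, rec in self.mtcod.items():
            if pid not in self.products:
                errors.append(f"MTCOD {pid}: unknown product")
            if rec.product_id != pid:
                errors.append(f"MTCOD key {pid} != record id {rec.product_id}")
        for (a, b), rec in self.mtcmd.items():
            for pid in (a, b):
                if pid not in self.products:
                    errors.append(f"MTCMD {a}->{b}: unknown product {pid}")
            if (rec.first_product_id, rec.second_product_id) != (a, b):
                errors.append(f"MTCMD key {a}->{b} != record ids")
        for i, r in enumerate(self.ddi):
            for ing in (r.ingredient_a, r.ingredient_b):
                if ing not in self.ingredients:
                    errors.append(f"DDI row {i}: unknown ingredient {ing}")
        seen: set[tuple[str, str]] = set()
        for i, r in enumerate(self.ddi):
            if r.canonical_pair in seen:
                errors.append(f"DDI row {i}: duplicate pair {r.canonical_pair} (dedupe first)")
            seen.add(r.canonical_pair)
        if errors:
            raise KBValidationError("KB validation failed:\n  " + "\n  ".join(errors))

    def ddi_lookup(self) -> dict[tuple[str, str], DDIRecord]:
        return {r.canonical_pair: r for r in self.ddi}


# ---------------------------------------------------------------------------
# summaries

def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percent_table(counts: Mapping[str, int]) -> pd.DataFrame:
    """Counts and percents (2 decimals, half-up) for a category tally.

    Percent columns sum to 100 within rounding (+-0.02).  An all-zero tally
    yields 0 percents and a ``degenerate`` flag.
    """
    total = int(sum(counts.values()))
    rows = []
    for key, n in counts.items():
        pct = _round2(100.0 * n / total) if total else 0.0
        rows.append({"category": key, "count": int(n), "percent": pct})
    df = pd.DataFrame(rows, columns=["category", "count", "percent"])
    df.attrs["total"] = total
    df.attrs["degenerate"] = total == 0
    return df


def severity_summary(kb_or_counts: KnowledgeBase | Mapping[str, int]) -> pd.DataFrame:
    """DDI severity composition (counts + percents).

    Accepts a KB (tallied over de-duplicated DDI records) or a raw
    ``{severity: count}`` mapping, e.g. published figure counts.
    """
    if isinstance(kb_or_counts, KnowledgeBase):
        recs = dedupe_ddi(kb_or_counts.ddi)
        counts = {s.value: 0 for s in Severity}
        for r in recs:
            counts[r.severity.value] += 1
    else:
        counts = dict(kb_or_counts)
    return percent_table(counts)


def ingredient_class_summary(kb_or_counts: KnowledgeBase | Mapping[str, int]) -> pd.DataFrame:
    """Ingredient class composition (chemical / TCM extract / natural product)."""
    if isinstance(kb_or_counts, KnowledgeBase):
        counts = {c.value: 0 for c in IngredientClass}
        for ing in kb_or_counts.ingredients.values():
            counts[ing.ingredient_class.value] += 1
    else:
        counts = dict(kb_or_counts)
    return percent_table(counts)


def product_summary(kb_or_counts: KnowledgeBase | Mapping[str, int]) -> pd.DataFrame:
    """Product composition by (OTC status x category) label.

    For a KB, products are tallied by ``{otc|non_otc}_{western|chinese_patent}``.
    """
    if isinstance(kb_or_counts, KnowledgeBase):
        counts: dict[str, int] = {}
        for p in kb_or_counts.products.values():
            key = ("otc" if p.otc else "non_otc") + "_" + p.category.value
            counts[key] = counts.get(key, 0) + 1
    else:
        counts = dict(kb_or_counts)
    return percent_table(counts)


# ---------------------------------------------------------------------------
# file I/O

_CSV_FILES = ("products.csv", "mtcod.csv", "mtcmd.csv", "ddi.csv", "ingredients.csv")


def _windows_to_str(ws: tuple[TimeWindow, ...]) -> str:
    return ";".join(f"{w.start:g}~{w.end:g}" for w in ws)


def _windows_from_str(s: str) -> tuple[TimeWindow, ...]:
    if not s or (isinstance(s, float) and math.isnan(s)):
        return ()
    out = []
    for chunk in str(s).split(";"):
        a, b = chunk.split("~")
        out.append(TimeWindow(snap(float(a)), snap(float(b))))
    return tuple(out)


def _product_to_row(p: PharmaceuticalProduct) -> dict:
    return {
        "product_id": p.product_id,
        "name": p.name,
        "otc": p.otc,
        "category": p.category.value,
        "origin": p.origin.value,
        "ingredient_ids": ";".join(p.ingredients),
    }


def _mtcod_to_row(r: MTCODRecord) -> dict:
    return {
        "product_id": r.product_id,
        "doses_per_day": r.doses_per_day,
        "min_isd": r.min_isd,
        "max_isd": r.max_isd,
        "meal_constraint": render_time_expr(r.meal_constraint) if r.meal_constraint else "",
        "chrono_windows": _windows_to_str(r.chrono_windows),
        "prn": r.prn,
    }


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("true", "1", "yes")


def _blank(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == ""


def kb_to_frames(kb: KnowledgeBase) -> dict[str, pd.DataFrame]:
    return {
        "products": pd.DataFrame([_product_to_row(p) for p in kb.products.values()]),
        "ingredients": pd.DataFrame(
            [
                {"ingredient_id": i.ingredient_id, "name": i.name, "ingredient_class": i.ingredient_class.value}
                for i in kb.ingredients.values()
            ]
        ),
        "mtcod": pd.DataFrame([_mtcod_to_row(r) for r in kb.mtcod.values()]),
        "mtcmd": pd.DataFrame(
            [
                {
                    "first_product_id": r.first_product_id,
                    "second_product_id": r.second_product_id,
                    "min_itd": r.min_itd,
                    "max_itd": r.max_itd,
                }
                for r in kb.mtcmd.values()
            ]
        ),
        "ddi": pd.DataFrame(
            [
                {
                    "ingredient_a": r.ingredient_a,
                    "ingredient_b": r.ingredient_b,
                    "severity": r.severity.value,
                    "mechanism_note": r.mechanism_note,
                    "source": r.source.value,
                }
                for r in kb.ddi
            ]
        ),
    }


def kb_from_frames(frames: Mapping[str, pd.DataFrame]) -> KnowledgeBase:
    kb = KnowledgeBase()
    errors: list[str] = []

    for i, row in frames.get("ingredients", pd.DataFrame()).iterrows():
        try:
            ing = Ingredient(str(row["ingredient_id"]), str(row["name"]), IngredientClass(row["ingredient_class"]))
            if ing.ingredient_id in kb.ingredients:
                errors.append(f"ingredients row {i}: duplicate ingredient_id {ing.ingredient_id}")
            kb.ingredients[ing.ingredient_id] = ing
        except (ValueError, KeyError) as e:
            errors.append(f"ingredients row {i}: {e}")

    for i, row in frames.get("products", pd.DataFrame()).iterrows():
        try:
            p = PharmaceuticalProduct(
                str(row["product_id"]),
                str(row["name"]),
                tuple(x for x in str(row["ingredient_ids"]).split(";") if x),
                _parse_bool(row["otc"]),
                ProductCategory(row["category"]),
                Origin(row["origin"]),
            )
            if p.product_id in kb.products:
                errors.append(f"products row {i}: duplicate product_id {p.product_id}")
            kb.products[p.product_id] = p
        except (ValueError, KeyError) as e:
            errors.append(f"products row {i}: {e}")

    for i, row in frames.get("mtcod", pd.DataFrame()).iterrows():
        try:
            expr = None if _blank(row.get("meal_constraint")) else parse_time_expr(str(row["meal_constraint"]))
            rec = MTCODRecord(
                str(row["product_id"]),
                int(row["doses_per_day"]),
                float(row["min_isd"]),
                float(row["max_isd"]),
                expr,
                _windows_from_str(row.get("chrono_windows", "")),
                _parse_bool(row.get("prn", False)),
            )
            kb.mtcod[rec.product_id] = rec
        except (ValueError, KeyError) as e:
            errors.append(f"mtcod row {i}: {e}")

    for i, row in frames.get("mtcmd", pd.DataFrame()).iterrows():
        try:
            rec = MTCMDRecord(
                str(row["first_product_id"]),
                str(row["second_product_id"]),
                float(row["min_itd"]),
                float(row["max_itd"]),
            )
            kb.mtcmd[(rec.first_product_id, rec.second_product_id)] = rec
        except (ValueError, KeyError) as e:
            errors.append(f"mtcmd row {i}: {e}")

    for i, row in frames.get("ddi", pd.DataFrame()).iterrows():
        try:
            kb.ddi.append(
                DDIRecord(
                    str(row["ingredient_a"]),
                    str(row["ingredient_b"]),
                    Severity(row["severity"]),
                    "" if _blank(row.get("mechanism_note")) else str(row["mechanism_note"]),
                    DDISource("A" if _blank(row.get("source")) else str(row["source"])),
                )
            )
        except (ValueError, KeyError) as e:
            errors.append(f"ddi row {i}: {e}")

    if errors:
        raise KBValidationError("KB load failed:\n  " + "\n  ".join(errors))
    kb.validate()
    return kb


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    """Write the KB: a ``*.json`` path gets one bundle file, a directory
    gets the five CSV tables."""
    path = Path(path)
    frames = kb_to_frames(kb)
    if path.suffix == ".json":
        bundle = {name: df.to_dict(orient="records") for name, df in frames.items()}
        path.write_text(json.dumps(bundle, indent=1, default=str), encoding="utf-8")
        return
    path.mkdir(parents=True, exist_ok=True)
    for name, df in frames.items():
        df.to_csv(path / f"{name}.csv", index=False)


def load_kb(path: str | Path) -> KnowledgeBase:
    """Load and fully validate a KB from a CSV directory or a JSON bundle."""
    path = Path(path)
    if path.is_file() and path.suffix == ".json":
        bundle = json.loads(path.read_text(encoding="utf-8"))
        frames = {name: pd.DataFrame(rows) for name, rows in bundle.items()}
    elif path.is_dir():
        frames = {}
        for fname in _CSV_FILES:
            f = path / fname
            if f.exists():
                frames[fname[:-4]] = pd.read_csv(f, keep_default_na=False, na_values=[])
    else:
        raise FileNotFoundError(f"no KB at {path}")
    return kb_from_frames(frames)
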