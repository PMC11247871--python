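"""Curated worked-example knowledge base and a seeded synthetic generator.

The worked-example KB carries the canonical interval facts of the domain:
the aspirin/ibuprofen order asymmetry (ibuprofen is safe 2 h after
aspirin, but aspirin needs a 24 h gap after ibuprofen), the 2 h window
after rifampicin during which CYP3A4-substrate induction is strongest, a
metformin-style with-meals product, a q12h extended-release opioid whose
Min-ISD and Max-ISD coincide at 12 h, plus bedtime, fasting and prn
products exercising the symbolic constraint language.  Interval values
are the published pharmacology numbers; everything else (identifiers,
names, OTC flags, Max-ITD defaults) is synthetic scaffolding and labelled
as such.

The synthetic generator emits fully validated KBs of configurable size
whose embedded "seed prescription" is feasible by construction: a
schedule is laid out first and the pairwise intervals are derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constraint_dsl import GRID, TimeWindow, parse_time_expr, snap
from .interaction_check import PatientProfile, Prescription, PrescriptionItem
from .knowledge_base import (
    DDIRecord,
    DDISource,
    Ingredient,
    IngredientClass,
    KnowledgeBase,
    MTCMDRecord,
    MTCODRecord,
    Origin,
    PharmaceuticalProduct,
    ProductCategory,
    Severity,
    compute_max_isd,
)

#: Published composition counts used as inputs to the summary operations.
PUBLISHED_SEVERITY_COUNTS = {
    "moderate": 155_650,
    "major": 47_408,
    # remainder of the 255,708 de-duplicated ingredient pairs
    "minor_or_unknown": 255_708 - 155_650 - 47_408,
}
PUBLISHED_INGREDIENT_CLASS_COUNTS = {
    "chemical": 5_786,
    "tcm_extract": 4_567,
    "natural_product": 269,  # remainder of 10,615 ingredients, published 2.44%
    "other": 10_615 - 5_786 - 4_567 - 269,
}
PUBLISHED_DOMESTIC_PRODUCT_COUNTS = {
    # 150,376 domestic products, of which 144,690 are non-OTC western
    "non_otc_western": 144_690,
    "other_domestic": 150_376 - 144_690,
}


def _product(pid, name, ings, otc=False):
    return PharmaceuticalProduct(
        product_id=pid,
        name=name,
        ingredients=tuple(ings),
        otc=otc,
        category=ProductCategory.WESTERN,
        origin=Origin.DOMESTIC,
    )


def worked_example_kb() -> KnowledgeBase:
    """The curated example KB (see module docstring for provenance)."""
    kb = KnowledgeBase()
    for iid, name in [
        ("ING_ASA", "aspirin"),
        ("ING_IBU", "ibuprofen"),
        ("ING_RIF", "rifampicin"),
        ("ING_SUB", "cyp3a4 substrate (synthetic)"),
        ("ING_MET", "metformin"),
        ("ING_OXY", "oxycodone"),
        ("ING_BED", "bedtime hypnotic (synthetic)"),
        ("ING_FAS", "fasting antibiotic (synthetic)"),
        ("ING_PRN", "rescue analgesic (synthetic)"),
    ]:
        kb.ingredients[iid] = Ingredient(iid, name, IngredientClass.CHEMICAL)

    products = [
        _product("ASP", "aspirin enteric-coated tablets", ["ING_ASA"]),
        _product("IBU", "ibuprofen tablets", ["ING_IBU"], otc=True),
        _product("RIF", "rifampicin capsules", ["ING_RIF"]),
        _product("SUB", "cyp3a4-substrate tablets (synthetic)", ["ING_SUB"]),
        _product("MET", "metformin hydrochloride tablets", ["ING_MET"]),
        _product("OXY", "oxycodone hydrochloride extended-release tablets", ["ING_OXY"]),
        _product("BED", "bedtime hypnotic tablets (synthetic)", ["ING_BED"]),
        _product("FAS", "fasting antibiotic capsules (synthetic)", ["ING_FAS"]),
        _product("PRN", "rescue analgesic tablets (synthetic)", ["ING_PRN"]),
    ]
    for p in products:
        kb.products[p.product_id] = p

    def mtcod(pid, doses, min_isd, max_isd=None, meal=None, prn=False):
        kb.mtcod[pid] = MTCODRecord(
            product_id=pid,
            doses_per_day=doses,
            min_isd=min_isd,
            max_isd=compute_max_isd(doses) if max_isd is None else max_isd,
            meal_constraint=parse_time_expr(meal) if meal else None,
            prn=prn,
        )

    mtcod("ASP", 1, 6.0)  # synthetic Min-ISD
    mtcod("IBU", 1, 4.0)  # synthetic Min-ISD
    mtcod("RIF", 1, 12.0)
    mtcod("SUB", 1, 6.0)
    mtcod("MET", 2, 4.0, meal="C0")  # with meals; synthetic Min-ISD
    mtcod("OXY", 2, 12.0, max_isd=12.0)  # q12h: Min-ISD = Max-ISD = 12 h
    mtcod("BED", 1, 12.0, meal="-S0.25~-S0.5")
    mtcod("FAS", 1, 8.0, meal="-C1;C2")
    mtcod("PRN", 1, 4.0, prn=True)

    def mtcmd(a, b, min_itd):
        # Max-ITD is not a published figure; synthetic default
        kb.mtcmd[(a, b)] = MTCMDRecord(a, b, min_itd, max(min_itd, 24.0 - min_itd))

    mtcmd("ASP", "IBU", 2.0)  # ibuprofen safe from 2 h after aspirin
    mtcmd("IBU", "ASP", 24.0)  # aspirin blunted unless 24 h after ibuprofen
    mtcmd("RIF", "SUB", 2.0)  # induction steady ~2 h after rifampicin
    mtcmd("SUB", "RIF", 0.25)  # synthetic

    kb.ddi = [
        DDIRecord("ING_ASA", "ING_IBU", Severity.MODERATE,
                  "ibuprofen competes for the platelet COX-1 site and can blunt aspirin's antiplatelet effect",
                  DDISource.A_SOURCE),
        DDIRecord("ING_RIF", "ING_SUB", Severity.MODERATE,
                  "rifampicin induces CYP3A4 and lowers substrate exposure",
                  DDISource.A_SOURCE),
        DDIRecord("ING_OXY", "ING_PRN", Severity.MINOR,
                  "additive sedation (synthetic note)", DDISource.B_SOURCE),
    ]
    kb.validate()
    return kb


# ---------------------------------------------------------------------------
# synthetic generator

@dataclass(frozen=True)
class SynthConfig:
    n_products: int = 12
    n_ingredients: int = 10
    ddi_density: float = 0.25
    severity_mix: tuple[float, float, float, float] = (0.19, 0.61, 0.1, 0.1)
    doses_range: tuple[int, int] = (1, 3)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.ddi_density <= 1:
            raise ValueError("ddi_density must be a probability")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.severity_mix):
            raise ValueError("severity_mix must be a probability vector summing to 1")
        lo, hi = self.doses_range
        if not (1 <= lo <= hi <= 4):
            raise ValueError("doses_range must lie within [1, 4]")
        if self.ddi_density > 0 and self.n_ingredients < 2:
            raise ValueError("ddi_density > 0 needs at least 2 ingredients")


_SEVERITIES = (Severity.MAJOR, Severity.MODERATE, Severity.MINOR, Severity.UNKNOWN)


def _seed_schedule_times(doses: int, wake: float, sleep: float, min_isd: float, max_isd: float,
                         start_offset: float) -> list[float]:
    """Evenly spread dose times inside the waking window, staggered by product."""
    start = snap(wake + start_offset)
    if doses == 1:
        return [start]
    span = sleep - start
    gap = min(max_isd, int(span / (doses - 1) / GRID) * GRID)
    return [snap(start + k * gap) for k in range(doses)]


def generate_kb_with_rx(config: SynthConfig) -> tuple[KnowledgeBase, Prescription]:
    """Seed-deterministic KB plus its feasible-by-construction prescription."""
    rng = np.random.default_rng(config.seed)
    kb = KnowledgeBase()

    classes = rng.choice(
        [c.value for c in IngredientClass], size=config.n_ingredients, p=[0.55, 0.43, 0.02]
    )
    for i in range(config.n_ingredients):
        iid = f"SI{i:04d}"
        kb.ingredients[iid] = Ingredient(iid, f"synthetic ingredient {i}", IngredientClass(classes[i]))
    ing_ids = list(kb.ingredients)

    wake, sleep = 7.0, 22.0
    centres_by_pid: dict[str, list[float]] = {}
    lo, hi = config.doses_range
    for j in range(config.n_products):
        pid = f"SP{j:04d}"
        n_ing = 1 + int(rng.random() < 0.25)
        ings = rng.choice(ing_ids, size=n_ing, replace=False)
        kb.products[pid] = PharmaceuticalProduct(
            product_id=pid,
            name=f"synthetic product {j}",
            ingredients=tuple(str(x) for x in ings),
            otc=bool(rng.random() < 0.3),
            category=ProductCategory.WESTERN if rng.random() < 0.9 else ProductCategory.CHINESE_PATENT,
            origin=Origin.DOMESTIC if rng.random() < 0.95 else Origin.IMPORTED,
        )
        doses = int(rng.integers(lo, hi + 1))
        max_isd = compute_max_isd(doses)
        # keep the seed layout feasible: doses-1 gaps of >= min_isd must fit the
        # waking span net of the per-product stagger (>= 14 h)
        cap = max_isd if doses == 1 else min(max_isd, int(14.0 / (doses - 1) / GRID) * GRID)
        min_isd = snap(float(rng.integers(1, max(1, int(cap / GRID)) + 1)) * GRID)
        min_isd = min(max(min_isd, GRID), cap)
        prn = rng.random() < 0.1
        # recommended-time windows (chronopharmacology slot per dose), centred
        # on an even in-day layout; once-daily products are sometimes free
        offset = float(rng.integers(0, 5)) * GRID
        centres = _seed_schedule_times(doses, wake, sleep, min_isd, max_isd, offset)
        centres_by_pid[pid] = centres
        chrono: tuple[TimeWindow, ...] = ()
        if not prn and not (doses == 1 and rng.random() < 0.4):
            chrono = tuple(
                TimeWindow(snap(max(0.0, c - 0.75)), snap(min(23.75, c + 0.75))) for c in centres
            )
        kb.mtcod[pid] = MTCODRecord(pid, doses, min_isd, max_isd, None, chrono, prn)

    # DDI records over canonical ingredient pairs
    for i in range(config.n_ingredients):
        for j in range(i + 1, config.n_ingredients):
            if rng.random() < config.ddi_density:
                sev = _SEVERITIES[int(rng.choice(4, p=list(config.severity_mix)))]
                kb.ddi.append(
                    DDIRecord(ing_ids[i], ing_ids[j], sev, "synthetic mechanism", DDISource.A_SOURCE)
                )

    # seed prescription: 2-3 non-prn, non-major products, feasible by construction
    ddi = {r.canonical_pair: r for r in kb.ddi}

    def pair_severity(a: str, b: str) -> Severity | None:
        best = None
        for ia in kb.products[a].ingredients:
            for ib in kb.products[b].ingredients:
                r = ddi.get(tuple(sorted((ia, ib))))
                if r and (best is None or r.severity.rank > best.rank):
                    best = r.severity
        return best

    candidates = [p for p in kb.products if not kb.mtcod[p].prn]
    seed_rx: list[str] = []
    for pid in candidates:
        if all(pair_severity(pid, q) is not Severity.MAJOR for q in seed_rx):
            seed_rx.append(pid)
        if len(seed_rx) == 3:
            break

    # the recommended-time centres double as the feasible seed layout
    layout = {pid: centres_by_pid[pid] for pid in seed_rx}

    # derive MTCMD intervals consistent with the layout for interacting pairs
    for i, a in enumerate(seed_rx):
        for b in seed_rx[i + 1 :]:
            if pair_severity(a, b) is None:
                continue
            for first, second in ((a, b), (b, a)):
                gaps = [
                    ts - tf
                    for tf in layout[first]
                    for ts in layout[second]
                    if ts >= tf
                ]
                min_itd = snap(min(gaps)) if gaps else 0.25
                min_itd = max(min_itd, 0.0)
                kb.mtcmd[(first, second)] = MTCMDRecord(first, second, min_itd, 24.0)

    # a few extra directional records between non-seed interacting products
    others = [p for p in kb.products if p not in seed_rx]
    for i, a in enumerate(others):
        for b in others[i + 1 :]:
            if pair_severity(a, b) is not None and rng.random() < 0.5:
                m = snap(float(rng.integers(1, 17)) * GRID)
                kb.mtcmd[(a, b)] = MTCMDRecord(a, b, m, max(m, 24.0 - m))

    kb.validate()
    rx = Prescription(
        items=tuple(PrescriptionItem(pid) for pid in seed_rx),
        profile=PatientProfile(),
    )
    return kb, rx


def generate_kb(config: SynthConfig) -> KnowledgeBase:
    """Seed-deterministic synthetic KB (see :func:`generate_kb_with_rx`)."""
    return generate_kb_with_rx(config)[0]
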