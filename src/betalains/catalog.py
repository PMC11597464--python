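"""Betalain catalog: data model, TSV I/O, class taxonomy, derivative
enumeration, betaxanthin condensation, and summary statistics.

The package ships a reference catalog of the 86 betalains reported in red
pitaya (``data/red_pitaya_catalog.tsv``) plus a table of named neutral
losses (``data/neutral_losses.tsv``).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .chem import (
    ElementComposition,
    compose_add,
    compose_subtract,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    protonated_mz,
    round_half_away,
)

log = logging.getLogger(__name__)

__all__ = [
    "BetalainClass",
    "BetalainRecord",
    "Catalog",
    "NeutralLoss",
    "NeutralLossTable",
    "BETACYANIN_FRAMEWORK_IONS",
    "AGLYCONE_MZ",
    "BETALAMIC_ACID",
    "CO2",
    "H2",
    "H2O",
    "load_catalog",
    "bundled_catalog_path",
    "bundled_catalog",
    "bundled_neutral_losses",
    "load_neutral_losses",
    "catalog_stats",
    "validate_catalog",
    "enumerate_derivatives",
    "condense_betaxanthin",
    "relative_rt",
    "derivative_ops_from_name",
    "base_name_from_derivative",
]

#: [M+H]+ of the deglycosylated betacyanin core (betanidin).
AGLYCONE_MZ = 389.0979

#: Class-specific framework ion [M+H]+ per betacyanin class.
BETACYANIN_FRAMEWORK_IONS: dict[str, float] = {
    "betanin-type": 551.1508,
    "amaranthin-type": 727.1829,
    "melocactin-type": 713.2036,
    "apiocactin-type": 683.1930,
    "gomphrenin-type": 551.1508,
    "glabranin-type": 713.2036,
}

_BETACYANIN_CLASSES = set(BETACYANIN_FRAMEWORK_IONS) | {"unknown-type"}
_BETAXANTHIN_CLASSES = {
    "hydrophobic",
    "polar-uncharged",
    "positively-charged",
    "negatively-charged",
    "special",
}

BETALAMIC_ACID = parse_formula("C9H9NO5")
CO2 = parse_formula("CO2")
H2 = parse_formula("H2")
H2O = parse_formula("H2O")

#: Formula/m/z consistency threshold in Da for catalog validation.
MZ_CONSISTENCY_DA = 0.0005


@dataclass(frozen=True)
class BetalainClass:
    """A betalain class with its parent branch and optional framework ion."""

    name: str
    parent: str  # betacyanin | betaxanthin | betalamic-acid
    framework_ion: float | None = None

    @classmethod
    def from_name(cls, name: str) -> "BetalainClass":
        if name in _BETACYANIN_CLASSES:
            return cls(name, "betacyanin", BETACYANIN_FRAMEWORK_IONS.get(name))
        if name in _BETAXANTHIN_CLASSES:
            return cls(name, "betaxanthin")
        if name == "betalamic-acid":
            return cls(name, "betalamic-acid")
        raise ValueError(f"unknown betalain class {name!r}")


@dataclass(frozen=True)
class BetalainRecord:
    """One catalog entry (a row of the reference table)."""

    id: int
    name: str
    category: str  # betacyanin | betacyanin-derivative | betaxanthin | betalamic-acid
    betalain_class: BetalainClass
    formula: ElementComposition
    rt: float
    relative_rt: float | None
    theoretical_mz: float
    observed_mz: float | None
    ppm: float | None
    fragments: tuple[float, ...]
    tentative: bool = False
    printed_label: str = ""
    reference: str = ""
    derivative_ops: tuple[str, ...] = ()

    @property
    def is_derivative(self) -> bool:
        return self.category == "betacyanin-derivative"

    @property
    def parent(self) -> str:
        return self.betalain_class.parent


@dataclass(frozen=True)
class NeutralLoss:
    name: str
    formula: ElementComposition
    mass: float


class NeutralLossTable:
    """Named residue losses keyed by monoisotopic mass."""

    def __init__(self, entries: Iterable[NeutralLoss]):
        self.entries = tuple(entries)
        for e in self.entries:
            delta = abs(e.mass - monoisotopic_mass(e.formula))
            if delta > 1e-4:
                raise ValueError(
                    f"loss {e.name}: tabulated mass {e.mass} inconsistent with "
                    f"formula {e.formula} by {delta:.6f} Da"
                )

    def __iter__(self) -> Iterator[NeutralLoss]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> NeutralLoss:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


class Catalog:
    """An ordered collection of :class:`BetalainRecord`."""

    def __init__(self, records: Iterable[BetalainRecord], reference_compound: str = "Betanin"):
        self.records = list(records)
        self.reference_compound = reference_compound
        seen = set()
        for r in self.records:
            key = (r.name, r.rt)
            if key in seen:
                raise ValueError(f"duplicate (name, rt) pair {key} in catalog")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BetalainRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> BetalainRecord:
        return self.records[idx]

    def by_name(self, name: str) -> BetalainRecord:
        for r in self.records:
            if r.name.lower() == name.lower():
                return r
        raise KeyError(name)

    @property
    def reference_record(self) -> BetalainRecord | None:
        try:
            return self.by_name(self.reference_compound)
        except KeyError:
            return None


# -- derivative-name grammar -------------------------------------------------

_DECARBOXY_RE = re.compile(r"(bi|tri)?des?carboxy", re.IGNORECASE)
_MULTIPLICITY = {None: 1, "bi": 2, "tri": 3}


def derivative_ops_from_name(name: str) -> tuple[str, ...]:
    """Infer derivative operations from a compound name.

    ``xan`` encodes 2,3-dehydrogenation and ``neo`` 14,15-dehydrogenation;
    ``decarboxy`` (with ``bi``/``tri`` multiplicity, also the ``descarboxy``
    spelling) encodes loss of CO2.  Positional digits are nominal only.
    """
    ops: list[str] = []
    m = _DECARBOXY_RE.search(name)
    if m:
        ops.extend(["decarboxy"] * _MULTIPLICITY[m.group(1)])
    lowered = name.lower()
    if "xan" in lowered and "betaxanthin" not in lowered:
        ops.append("dehydro-2,3")
    if "neo" in lowered:
        ops.append("dehydro-14,15")
    if "2,3-dehydro" in lowered:
        ops.append("dehydro-2,3")
    if "14,15-dehydro" in lowered or "14, 15-dehydro" in lowered:
        ops.append("dehydro-14,15")
    return tuple(ops)


def base_name_from_derivative(name: str) -> str:
    """Strip derivative prefixes, leaving the unmodified compound name."""
    base = re.sub(r"(\d+[,\d]*-)?(bi|tri)?des?carboxy-", "", name, flags=re.IGNORECASE)
    base = re.sub(r"(2,3|14,\s?15)-dehydro-?", "", base, flags=re.IGNORECASE)
    base = base.replace("xan", "").replace("neo", "").replace("Neo", "")
    base = re.sub(r"^-+|-+$", "", base.strip())
    return base


_OP_DELTAS = {
    "decarboxy": CO2,
    "dehydro-2,3": H2,
    "dehydro-14,15": H2,
}

_OP_PREFIX = {
    "decarboxy": "decarboxy-",
    "dehydro-2,3": "xan",
    "dehydro-14,15": "neo",
}


def enumerate_derivatives(
    base: BetalainRecord, ops_list: Iterable[Iterable[str]]
) -> list[BetalainRecord]:
    """Build derivative records from a base compound and operation lists.

    Each inner iterable of *ops_list* is applied as a whole (e.g.
    ``["decarboxy", "decarboxy", "dehydro-2,3"]``); the derivative formula is
    the base formula minus one CO2 per decarboxylation and one H2 per
    dehydrogenation.  Mass is position-independent.
    """
    if base.is_derivative:
        raise ValueError(f"base compound {base.name!r} is itself a derivative")
    out: list[BetalainRecord] = []
    for ops in ops_list:
        ops = tuple(ops)
        if ops.count("decarboxy") > 3:
            raise ValueError("at most 3 decarboxylations supported")
        comp = base.formula
        for op in ops:
            try:
                comp = compose_subtract(comp, _OP_DELTAS[op])
            except KeyError:
                raise ValueError(f"unknown derivative op {op!r}") from None
        if not ops:
            out.append(base)
            continue
        prefix = "".join(_OP_PREFIX[op] for op in ops)
        out.append(
            replace(
                base,
                name=f"{prefix}{base.name[0].lower()}{base.name[1:]}",
                category="betacyanin-derivative",
                formula=comp,
                theoretical_mz=protonated_mz(comp),
                observed_mz=None,
                ppm=None,
                derivative_ops=ops,
            )
        )
    return out


def condense_betaxanthin(
    amine: ElementComposition, name: str, betalain_class: str = "hydrophobic"
) -> BetalainRecord:
    """Condense betalamic acid with an amino acid / amine (loss of water)."""
    if amine["N"] < 1:
        raise ValueError("amine component must contain at least one nitrogen")
    comp = compose_subtract(compose_add(BETALAMIC_ACID, amine), H2O)
    return BetalainRecord(
        id=0,
        name=name,
        category="betaxanthin",
        betalain_class=BetalainClass.from_name(betalain_class),
        formula=comp,
        rt=float("nan"),
        relative_rt=None,
        theoretical_mz=protonated_mz(comp),
        observed_mz=None,
        ppm=None,
        fragments=(),
    )


def relative_rt(rt: float, reference_rt: float, decimals: int = 2) -> float:
    """Retention time expressed relative to the reference compound."""
    if reference_rt <= 0:
        raise ValueError(f"reference retention time must be positive, got {reference_rt}")
    return round_half_away(rt / reference_rt, decimals)


# -- I/O ---------------------------------------------------------------------

_SCHEMA = [
    "id",
    "printed_label",
    "name",
    "category",
    "class",
    "formula",
    "rt_min",
    "relative_rt",
    "theoretical_mz",
    "observed_mz",
    "ppm",
    "fragments",
    "tentative",
    "reference",
]

_CATEGORY_TO_CLASS_PARENT = {
    "betacyanin": "betacyanin",
    "betacyanin-derivative": "betacyanin",
    "betaxanthin": "betaxanthin",
    "betalamic-acid": "betalamic-acid",
}


def load_catalog(path: str | Path, reference_compound: str = "Betanin") -> Catalog:
    """Load a catalog from a UTF-8 TSV file with the documented schema.

    A record whose printed theoretical m/z disagrees with its formula by more
    than 0.0005 Da is kept but logged as a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).fillna("")
    missing = [c for c in _SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path} missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        category = row["category"].strip()
        if category not in _CATEGORY_TO_CLASS_PARENT:
            raise ValueError(f"unknown category {category!r} in catalog row {row['id']}")
        comp = parse_formula(row["formula"])
        theoretical = float(row["theoretical_mz"])
        recomputed = protonated_mz(comp, decimals=None)
        if abs(recomputed - theoretical) > MZ_CONSISTENCY_DA:
            log.warning(
                "catalog row %s (%s): printed theoretical m/z %.4f differs from "
                "formula-derived %.4f by %.4f Da",
                row["id"], row["name"], theoretical, recomputed,
                abs(recomputed - theoretical),
            )
        fragments = tuple(
            float(tok) for tok in row["fragments"].split(";") if tok.strip()
        )
        records.append(
            BetalainRecord(
                id=int(row["id"]),
                name=row["name"].strip(),
                category=category,
                betalain_class=BetalainClass.from_name(row["class"].strip()),
                formula=comp,
                rt=float(row["rt_min"]),
                relative_rt=float(row["relative_rt"]) if row["relative_rt"] else None,
                theoretical_mz=theoretical,
                observed_mz=float(row["observed_mz"]) if row["observed_mz"] else None,
                ppm=float(row["ppm"]) if row["ppm"] else None,
                fragments=fragments,
                tentative=row["tentative"].strip() == "1",
                printed_label=row["printed_label"].strip(),
                reference=row["reference"].strip(),
                derivative_ops=derivative_ops_from_name(row["name"]),
            )
        )
    log.info("loaded %d catalog records from %s", len(records), path)
    return Catalog(records, reference_compound=reference_compound)


def bundled_catalog_path() -> Path:
    return Path(resources.files("betalains") / "data" / "red_pitaya_catalog.tsv")


def bundled_catalog() -> Catalog:
    """The red-pitaya reference catalog shipped with the package."""
    return load_catalog(bundled_catalog_path())


def load_neutral_losses(path: str | Path) -> NeutralLossTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return NeutralLossTable(
        NeutralLoss(row["name"], parse_formula(row["formula"]), float(row["mass"]))
        for _, row in df.iterrows()
    )


def bundled_neutral_losses() -> NeutralLossTable:
    return load_neutral_losses(
        Path(resources.files("betalains") / "data" / "neutral_losses.tsv")
    )


# -- statistics and validation ----------------------------------------------

def catalog_stats(catalog: Catalog) -> dict:
    """Summary counts per category, parent branch, and class, plus m/z range.

    ``abstract_partition`` merges the betalamic-acid record into the
    betacyanin bucket, matching the convention used when the catalog is
    summarised as "<betacyanins> + <derivatives> + <betaxanthins>".
    """
    by_category: dict[str, int] = {}
    by_parent: dict[str, int] = {}
    by_class: dict[str, int] = {}
    mzs = []
    tentative = 0
    for r in catalog:
        by_category[r.category] = by_category.get(r.category, 0) + 1
        by_parent[r.parent] = by_parent.get(r.parent, 0) + 1
        by_class[r.betalain_class.name] = by_class.get(r.betalain_class.name, 0) + 1
        mzs.append(r.theoretical_mz)
        tentative += r.tentative
    total = len(catalog)
    abstract = {
        "betacyanin": by_category.get("betacyanin", 0) + by_category.get("betalamic-acid", 0),
        "betacyanin-derivative": by_category.get("betacyanin-derivative", 0),
        "betaxanthin": by_category.get("betaxanthin", 0),
    }
    return {
        "total": total,
        "by_category": by_category,
        "by_parent": by_parent,
        "by_class": by_class,
        "abstract_partition": abstract,
        "tentative": tentative,
        "mz_range": (min(mzs), max(mzs)) if mzs else (None, None),
        "percent_by_parent": {
            k: round_half_away(100.0 * v / total, 1) for k, v in by_parent.items()
        } if total else {},
    }


def validate_catalog(catalog: Catalog, mz_tol: float = MZ_CONSISTENCY_DA) -> pd.DataFrame:
    """Per-record consistency checks against the chemistry layer.

    Columns: recomputed theoretical m/z from the formula (pass at *mz_tol*),
    recomputed ppm from the printed observed and theoretical m/z (pass within
    0.05 ppm after rounding to the printed precision), and recomputed
    relative Rt (pass within 0.01).
    """
    ref = catalog.reference_record
    rows = []
    for r in catalog:
        recomputed_mz = protonated_mz(r.formula, decimals=None)
        mz_delta = recomputed_mz - r.theoretical_mz
        if r.observed_mz is not None and r.ppm is not None:
            recomputed_ppm = ppm_error(r.observed_mz, r.theoretical_mz)
            printed_decimals = _decimals(r.ppm)
            ppm_delta = round_half_away(recomputed_ppm, printed_decimals) - r.ppm
            ppm_pass = abs(ppm_delta) <= 0.05 + 1e-9
        else:
            recomputed_ppm, ppm_delta, ppm_pass = math.nan, math.nan, True
        if ref is not None and r.relative_rt is not None:
            recomputed_rrt = relative_rt(r.rt, ref.rt)
            rrt_delta = recomputed_rrt - r.relative_rt
            rrt_pass = abs(rrt_delta) <= 0.01 + 1e-9
        else:
            recomputed_rrt, rrt_delta, rrt_pass = math.nan, math.nan, True
        rows.append(
            {
                "id": r.id,
                "name": r.name,
                "recomputed_mz": recomputed_mz,
                "mz_delta": mz_delta,
                "mz_pass": abs(mz_delta) <= mz_tol,
                "recomputed_ppm": recomputed_ppm,
                "ppm_delta": ppm_delta,
                "ppm_pass": ppm_pass,
                "recomputed_relative_rt": recomputed_rrt,
                "relative_rt_delta": rrt_delta,
                "relative_rt_pass": rrt_pass,
            }
        )
    return pd.DataFrame(rows)


def _decimals(x: float) -> int:
    """Number of decimals in a value as printed (via its repr)."""
    text = f"{x}"
    return len(text.split(".")[1]) if "." in text else 0
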