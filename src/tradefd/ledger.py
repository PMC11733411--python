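"""Trade-ledger ETL: parsing, filtering, whole-organism-equivalent conversion,
and aggregation into assemblage-by-species volume matrices.

The ledger model follows the CITES trade-database dialect: one row per
exporter-reported directional shipment, with term/unit describing what was
shipped (live animals, skins, kilograms of meat, ...), single-letter source
and purpose codes, and an optional origin country that differs from the
exporter on re-exports.  Quantities in heterogeneous terms are made
comparable by converting every record to whole-organism equivalents (WOE):
count-like terms map one-for-one (or by a fixed factor) to organisms, and
mass-based terms are divided by species body mass.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TradeRecord",
    "FilterSpec",
    "WOERule",
    "WOETable",
    "WOEEvent",
    "ParsedLedger",
    "AssemblageMatrix",
    "ExclusionReport",
    "DEFAULT_SCHEMA",
    "SOURCE_CLASSES",
    "parse_ledger",
    "filter_records",
    "to_woe",
    "convert_to_woe",
    "default_woe_table",
    "build_matrix",
    "exclude_sparse",
]

#: CITES source-code groupings: wild-sourced vs captive-produced specimens.
SOURCE_CLASSES: dict[str, frozenset[str]] = {
    "wild": frozenset({"W", "X", "R"}),
    "captive": frozenset({"C", "D", "F"}),
    "both": frozenset({"W", "X", "R", "C", "D", "F"}),
}

#: Canonical field -> column header in the deposited ledger dialect.
DEFAULT_SCHEMA: dict[str, str] = {
    "year": "Year",
    "taxon": "Taxon",
    "appendix": "App.",
    "term": "Term",
    "unit": "Unit",
    "quantity": "Quantity",
    "exporter": "Exporter",
    "importer": "Importer",
    "origin": "Origin",
    "source": "Source",
    "purpose": "Purpose",
}

_REQUIRED_FIELDS = ("year", "taxon", "term", "quantity", "exporter", "importer")
_OPTIONAL_FIELDS = ("appendix", "unit", "origin", "source", "purpose")


@dataclass(frozen=True)
class TradeRecord:
    """One directional shipment from the trade ledger."""

    year: int
    taxon: str
    term: str
    quantity: float
    exporter: str
    importer: str
    appendix: str = ""
    unit: str = ""  # blank unit means the quantity is a specimen count
    origin: str = ""
    source: str = ""
    purpose: str = ""

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError(f"negative quantity {self.quantity} for {self.taxon}")

    @property
    def is_reexport(self) -> bool:
        """A shipment whose declared origin differs from the exporter."""
        return bool(self.origin) and self.origin != self.exporter


@dataclass
class ParsedLedger:
    records: list[TradeRecord]
    rejected: list[tuple[int, str]]  # (1-based data line number, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def parse_ledger(
    path, schema: Mapping[str, str] | None = None
) -> ParsedLedger:
    """Read a shipment ledger CSV into :class:`TradeRecord` objects.

    ``schema`` maps canonical field names (``year``, ``taxon``, ``term``,
    ``unit``, ``quantity``, ``exporter``, ``importer``, ``origin``,
    ``source``, ``purpose``, ``appendix``) to the file's column headers;
    the default matches the deposited CITES-dialect headers.  Rows whose
    quantity or year cannot be parsed are rejected and reported with their
    line number rather than aborting the whole read.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [schema[f] for f in _REQUIRED_FIELDS if schema[f] not in df.columns]
    if missing:
        raise ValueError(f"ledger is missing mapped columns: {missing}")

    records: list[TradeRecord] = []
    rejected: list[tuple[int, str]] = []
    has_opt = {f: schema[f] in df.columns for f in _OPTIONAL_FIELDS}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            year = int(row[schema["year"]])
        except ValueError:
            rejected.append((i, f"unparseable year {row[schema['year']]!r}"))
            continue
        try:
            quantity = float(row[schema["quantity"]])
        except ValueError:
            rejected.append((i, f"unparseable quantity {row[schema['quantity']]!r}"))
            continue
        if quantity < 0:
            rejected.append((i, f"negative quantity {quantity}"))
            continue
        opt = {
            f: str(row[schema[f]]).strip() if has_opt[f] else ""
            for f in _OPTIONAL_FIELDS
        }
        records.append(
            TradeRecord(
                year=year,
                taxon=str(row[schema["taxon"]]).strip(),
                term=str(row[schema["term"]]).strip().lower(),
                quantity=quantity,
                exporter=str(row[schema["exporter"]]).strip(),
                importer=str(row[schema["importer"]]).strip(),
                **opt,
            )
        )
    return ParsedLedger(records=records, rejected=rejected)


@dataclass(frozen=True)
class FilterSpec:
    """Which shipments enter the analysis.

    ``source_class`` selects wild-sourced (codes W, X, R) or captive-produced
    (codes C, D, F) specimens; commercial purposes default to P and T; records
    outside the year range, and re-exports (origin present and different from
    the exporter) when ``drop_reexports``, are removed.
    """

    source_class: str = "wild"
    purposes: frozenset[str] = frozenset({"P", "T"})
    years: tuple[int, int] = (2000, 2020)
    drop_reexports: bool = True

    def __post_init__(self) -> None:
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(f"unknown source class {self.source_class!r}")
        if self.years[0] > self.years[1]:
            raise ValueError("empty year range")
        object.__setattr__(self, "purposes", frozenset(self.purposes))


def filter_records(
    records: Iterable[TradeRecord],
    spec: FilterSpec,
    delisting_year: Mapping[str, int] | None = None,
) -> list[TradeRecord]:
    """Apply source/purpose/year/re-export filters to parsed records.

    ``delisting_year`` optionally maps species removed from the listings
    mid-period to their removal year; their records in later years are
    excluded.  The operation is idempotent.
    """
    sources = SOURCE_CLASSES[spec.source_class]
    lo, hi = spec.years
    out = []
    for r in records:
        if r.source not in sources:
            continue
        if r.purpose not in spec.purposes:
            continue
        if not (lo <= r.year <= hi):
            continue
        if spec.drop_reexports and r.is_reexport:
            continue
        if delisting_year is not None:
            dy = delisting_year.get(r.taxon)
            if dy is not None and r.year > dy:
                continue
        out.append(r)
    return out


@dataclass(frozen=True)
class WOERule:
    """How one (term, unit) combination converts to whole organisms.

    kind ``count_factor``: WOE = quantity x factor (e.g. one skin = one
    organism).  kind ``mass_based``: quantity is a mass in ``mass_unit``;
    WOE = mass in grams / species body mass in grams.  kind ``drop``:
    the term is not convertible and the record is dropped with a log entry.
    """

    kind: str
    factor: float = 1.0
    mass_unit: str = "kg"

    def __post_init__(self) -> None:
        if self.kind not in ("count_factor", "mass_based", "drop"):
            raise ValueError(f"unknown WOE rule kind {self.kind!r}")
        if self.kind == "count_factor" and self.factor <= 0:
            raise ValueError("count factor must be positive")
        if self.kind == "mass_based" and self.mass_unit not in ("kg", "g"):
            raise ValueError(f"unsupported mass unit {self.mass_unit!r}")


@dataclass(frozen=True)
class WOEEvent:
    """One logged drop/irregularity during WOE conversion."""

    record: TradeRecord
    reason: str


@dataclass
class WOETable:
    """Lookup of (term, unit) -> :class:`WOERule`.

    ``unknown_policy`` controls unmapped combinations: ``"drop"`` logs and
    discards them, ``"error"`` raises.
    """

    rules: dict[tuple[str, str], WOERule] = field(default_factory=dict)
    unknown_policy: str = "drop"

    def lookup(self, term: str, unit: str) -> WOERule | None:
        return self.rules.get((term.lower(), unit.lower()))


def default_woe_table(pair_factor: float = 1.0) -> WOETable:
    """A documented default conversion table.

    Count-like terms (live animals, bodies, skins, skulls, trophies) convert
    one-for-one; paired items use ``pair_factor`` per pair; meat shipped by
    mass is divided by species body mass; residual derivative terms are
    dropped.  Users substitute a published mapping by building their own
    :class:`WOETable`.
    """
    rules: dict[tuple[str, str], WOERule] = {}
    for term in ("live", "bodies", "skins", "skulls", "trophies"):
        rules[(term, "")] = WOERule("count_factor", factor=1.0)
    rules[("shoes", "pairs")] = WOERule("count_factor", factor=pair_factor)
    rules[("meat", "kg")] = WOERule("mass_based", mass_unit="kg")
    rules[("meat", "g")] = WOERule("mass_based", mass_unit="g")
    for term in ("derivatives", "medicine", "extract", "powder"):
        rules[(term, "")] = WOERule("drop")
        rules[(term, "kg")] = WOERule("drop")
    return WOETable(rules=rules)


def to_woe(
    record: TradeRecord,
    table: WOETable,
    body_mass_g: float | None = None,
    log: list[WOEEvent] | None = None,
) -> float:
    """Convert one record's quantity to whole-organism equivalents.

    Returns 0.0 (never silently: a :class:`WOEEvent` is appended to ``log``)
    when the record is dropped — unknown term under the drop policy, an
    explicit drop rule, or a mass-based term with no body mass available.
    ``to_woe`` is homogeneous of degree 1 in the quantity.
    """
    rule = table.lookup(record.term, record.unit)
    if rule is None:
        if table.unknown_policy == "error":
            raise KeyError(f"no WOE rule for ({record.term!r}, {record.unit!r})")
        if log is not None:
            log.append(WOEEvent(record, f"unknown term/unit ({record.term!r}, {record.unit!r})"))
        return 0.0
    if rule.kind == "drop":
        if log is not None:
            log.append(WOEEvent(record, f"term {record.term!r} mapped to drop"))
        return 0.0
    if rule.kind == "count_factor":
        return record.quantity * rule.factor
    # mass_based
    if body_mass_g is None or body_mass_g <= 0:
        if log is not None:
            log.append(WOEEvent(record, f"mass-based term {record.term!r} with no body mass"))
        return 0.0
    grams = record.quantity * (1000.0 if rule.mass_unit == "kg" else 1.0)
    return grams / body_mass_g


def convert_to_woe(
    records: Iterable[TradeRecord],
    table: WOETable,
    body_mass_g: Mapping[str, float] | None = None,
) -> tuple[list[tuple[TradeRecord, float]], list[WOEEvent]]:
    """WOE-convert a batch; returns (record, woe) pairs and the drop log.

    Records converting to zero WOE (drops) are excluded from the pairs and
    appear only in the log.
    """
    body_mass_g = body_mass_g or {}
    log: list[WOEEvent] = []
    pairs = []
    for r in records:
        w = to_woe(r, table, body_mass_g.get(r.taxon), log=log)
        if w > 0:
            pairs.append((r, w))
    return pairs, log


GROUPINGS = (
    "exporter",
    "importer",
    "route",
    "exporter_continent",
    "importer_continent",
    "continental_route",
)

_THREAT_CLASS = {
    "CR": "threatened", "EN": "threatened", "VU": "threatened",
    "NT": "non_threatened", "LC": "non_threatened",
}


@dataclass
class AssemblageMatrix:
    """Assemblage x species matrix of summed WOE volumes.

    Rows are assemblage keys (a grouping level plus optional strata: year,
    live/dead market, threat class); columns are the full configured species
    pool, so species never recorded in trade appear as all-zero columns.
    """

    data: pd.DataFrame  # MultiIndex rows (key fields), columns = species pool
    grouping: str
    strata: tuple[str, ...] = ()

    @property
    def pool(self) -> list[str]:
        return list(self.data.columns)

    @property
    def total_woe(self) -> float:
        return float(self.data.to_numpy().sum())

    def species_counts(self) -> pd.Series:
        """Number of species with positive volume per assemblage."""
        return (self.data > 0).sum(axis=1)

    def to_csv(self, path) -> None:
        """Wide CSV: key fields first, then one column per pool species."""
        self.data.reset_index().to_csv(path, index=False)


def _record_key(
    r: TradeRecord,
    grouping: str,
    continent_map: Mapping[str, str] | None,
) -> tuple:
    def cont(country: str) -> str:
        if continent_map is None or country not in continent_map:
            raise KeyError(f"no continent mapping for country {country!r}")
        return continent_map[country]

    if grouping == "exporter":
        return (r.exporter,)
    if grouping == "importer":
        return (r.importer,)
    if grouping == "route":
        return (r.exporter, r.importer)
    if grouping == "exporter_continent":
        return (cont(r.exporter),)
    if grouping == "importer_continent":
        return (cont(r.importer),)
    if grouping == "continental_route":
        return (cont(r.exporter), cont(r.importer))
    raise ValueError(f"unknown grouping {grouping!r}; choose from {GROUPINGS}")


_KEY_NAMES = {
    "exporter": ("exporter",),
    "importer": ("importer",),
    "route": ("exporter", "importer"),
    "exporter_continent": ("exporter_continent",),
    "importer_continent": ("importer_continent",),
    "continental_route": ("exporter_continent", "importer_continent"),
}


def build_matrix(
    woe_records: Sequence[tuple[TradeRecord, float]],
    grouping: str,
    pool: Sequence[str],
    strata: Sequence[str] = (),
    continent_map: Mapping[str, str] | None = None,
    iucn: Mapping[str, str] | None = None,
    live_terms: frozenset[str] | set[str] = frozenset({"live"}),
) -> AssemblageMatrix:
    """Aggregate WOE-converted records into an assemblage matrix.

    ``strata`` may include ``"year"``, ``"market"`` (live vs dead specimens,
    assigned from the term via ``live_terms``) and ``"threat"`` (IUCN CR/EN/VU
    = threatened, NT/LC = non-threatened; Data Deficient and unassessed
    species are excluded from threat-stratified matrices).  Columns are the
    full species pool; non-traded pool species keep all-zero columns.
    """
    strata = tuple(strata)
    for s in strata:
        if s not in ("year", "market", "threat"):
            raise ValueError(f"unknown stratum {s!r}")
    pool = list(pool)
    pool_set = set(pool)
    offenders = sorted({r.taxon for r, _ in woe_records} - pool_set)
    if offenders:
        raise ValueError(f"species in records absent from pool: {offenders}")
    if "threat" in strata and iucn is None:
        raise ValueError("threat stratum requires an IUCN category mapping")

    cells: dict[tuple, dict[str, float]] = {}
    for r, w in woe_records:
        key = list(_record_key(r, grouping, continent_map))
        skip = False
        for s in strata:
            if s == "year":
                key.append(r.year)
            elif s == "market":
                key.append("live" if r.term in live_terms else "dead")
            else:  # threat
                tc = _THREAT_CLASS.get(iucn.get(r.taxon, "NE"))
                if tc is None:
                    skip = True
                    break
                key.append(tc)
        if skip:
            continue
        row = cells.setdefault(tuple(key), {})
        row[r.taxon] = row.get(r.taxon, 0.0) + w

    names = _KEY_NAMES[grouping] + strata
    if cells:
        index = pd.MultiIndex.from_tuples(sorted(cells), names=names)
        data = pd.DataFrame(0.0, index=index, columns=pool)
        for key, row in cells.items():
            for sp, w in row.items():
                data.loc[key, sp] = w
    else:
        index = pd.MultiIndex.from_tuples([], names=names)
        data = pd.DataFrame(0.0, index=index, columns=pool)
    return AssemblageMatrix(data=data, grouping=grouping, strata=strata)


@dataclass
class ExclusionReport:
    """Assemblages dropped by the sparse-row rule and their trade share."""

    dropped: pd.DataFrame  # index = dropped keys; columns n_species, woe
    total_woe: float

    @property
    def dropped_woe(self) -> float:
        return float(self.dropped["woe"].sum())

    @property
    def dropped_share(self) -> float:
        """Share of total WOE carried by dropped assemblages, in [0, 1]."""
        return self.dropped_woe / self.total_woe if self.total_woe > 0 else 0.0


def exclude_sparse(
    matrix: AssemblageMatrix, min_species: int = 4
) -> tuple[AssemblageMatrix, ExclusionReport]:
    """Drop assemblages with fewer than ``min_species`` traded species.

    Functional metrics need at least one species more than the number of
    functional axes, so with a 3-axis space assemblages of three or fewer
    species are excluded (the default).  The report lists dropped keys, their
    species counts, and their share of total WOE volume.
    """
    if min_species < 1:
        raise ValueError("min_species must be >= 1")
    counts = matrix.species_counts()
    keep = counts >= min_species
    dropped = pd.DataFrame(
        {
            "n_species": counts[~keep],
            "woe": matrix.data[~keep].sum(axis=1),
        }
    )
    report = ExclusionReport(dropped=dropped, total_woe=matrix.total_woe)
    kept = dataclasses.replace(matrix, data=matrix.data[keep])
    return kept, report
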