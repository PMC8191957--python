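"""Typed records for the swimming-microorganism trait tables.

The literature tables this package ingests report each measured trait in a
compact printed notation: a mean, optionally a standard deviation after a
``±`` sign, optionally a measured range in parentheses, and sometimes only an
upper bound introduced by ``max``.  :func:`parse_quantity` understands that
grammar; :class:`Quantity` stores the pieces exactly as printed (no unit
conversion happens here), and :func:`collapse` reduces a quantity to the
single number the propulsion models consume.

All lengths are in micrometres, speeds in micrometres per second and
frequencies in cycles per second unless a field says otherwise.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass

__all__ = [
    "Quantity",
    "OrganismRecord",
    "CollapsePolicy",
    "QuantityParseError",
    "parse_quantity",
    "format_quantity",
    "collapse",
    "read_records",
    "write_records",
    "GROUPS",
]

GROUPS = frozenset(
    {
        "bacteria",
        "spirochaete",
        "spiroplasma",
        "archaea",
        "flagellate",
        "spermatozoon",
        "ciliate",
    }
)

# Footnote/provenance markers that appear attached to printed numbers.
_MARKERS = "†‡⋆×♢♣♠♯*"

_NUM = r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"


class QuantityParseError(ValueError):
    """Raised when a printed cell does not match the value grammar."""

    def __init__(self, text: str, reason: str = "does not match value grammar"):
        self.text = text
        super().__init__(f"cannot parse quantity {text!r}: {reason}")


@dataclass(frozen=True)
class Quantity:
    """A printed measurement: point value, spread and/or range.

    ``bound_only`` is set when the table printed only an upper bound
    (``max ...``); ``hi`` then carries that bound.
    """

    point: float | None = None
    sd: float | None = None
    lo: float | None = None
    hi: float | None = None
    bound_only: bool = False

    def __post_init__(self) -> None:
        if self.point is None and self.lo is None and self.hi is None:
            raise ValueError("empty Quantity: need at least one of point/lo/hi")
        if self.sd is not None:
            if self.sd < 0:
                raise ValueError("sd must be >= 0")
            if self.point is None:
                raise ValueError("sd requires a point value")
        if self.lo is not None and self.hi is not None and self.lo > self.hi:
            raise ValueError(f"lo={self.lo} > hi={self.hi}")

    def validation_warnings(self) -> list[str]:
        """Non-fatal oddities (the source tables occasionally contain them)."""
        w = []
        if (
            self.point is not None
            and self.lo is not None
            and self.hi is not None
            and not (self.lo <= self.point <= self.hi)
        ):
            w.append(f"point {self.point} outside printed range ({self.lo} - {self.hi})")
        return w

    def scaled(self, c: float) -> "Quantity":
        """Multiply every stored value by ``c > 0`` (for unit changes)."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        sc = lambda v: None if v is None else c * v
        return Quantity(sc(self.point), sc(self.sd), sc(self.lo), sc(self.hi), self.bound_only)

    def to_dict(self) -> dict:
        d: dict = {}
        for name in ("point", "sd", "lo", "hi"):
            v = getattr(self, name)
            if v is not None:
                d[name] = v
        if self.bound_only:
            d["bound_only"] = True
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Quantity":
        return cls(
            point=d.get("point"),
            sd=d.get("sd"),
            lo=d.get("lo"),
            hi=d.get("hi"),
            bound_only=bool(d.get("bound_only", False)),
        )


def _fnum(s: str) -> float:
    return float(s.replace("−", "-"))


def _strip_markers(text: str) -> str:
    return "".join(ch for ch in text if ch not in _MARKERS)


# One regex for the whole grammar:  a | a ± s | (a − b) | max b | a ± s (max b)
# | a (b − c) | a ± s (b − c).  Dashes inside ranges may be -, − or –.
_CELL_RE = re.compile(
    rf"""^\s*
    (?:(?P<point>{_NUM})\s*)?                    # optional point value
    (?:±\s*(?P<sd>{_NUM})\s*)?                   # optional ± sd
    (?:
        \(\s*(?:
            max\s*(?P<pmax>{_NUM})               # (max b)
            |
            (?P<plo>{_NUM})\s*[-−–]\s*(?P<phi>{_NUM})   # (b − c)
        )\s*\)
        |
        max\s*(?P<bmax>{_NUM})                   # bare max b
    )?\s*$""",
    re.VERBOSE,
)


def parse_quantity(text: str) -> Quantity:
    """Parse one printed table cell into a :class:`Quantity`.

    Footnote markers (``†``, ``‡``, ``⋆``, ``×``, ...) are stripped before
    matching; the caller is expected to keep the raw text for provenance.
    """
    cleaned = _strip_markers(text).replace("−", "-").strip()
    if not cleaned:
        raise QuantityParseError(text, "empty cell")
    m = _CELL_RE.match(cleaned)
    if m is None:
        raise QuantityParseError(text)
    g = m.groupdict()
    point = _fnum(g["point"]) if g["point"] else None
    sd = _fnum(g["sd"]) if g["sd"] else None
    lo = hi = None
    bound_only = False
    if g["pmax"] or g["bmax"]:
        hi = _fnum(g["pmax"] or g["bmax"])
        bound_only = point is None
    elif g["plo"]:
        lo, hi = _fnum(g["plo"]), _fnum(g["phi"])
    if point is None and sd is not None:
        raise QuantityParseError(text, "± without a leading value")
    if point is None and lo is None and hi is None:
        raise QuantityParseError(text)
    try:
        return Quantity(point=point, sd=sd, lo=lo, hi=hi, bound_only=bound_only)
    except ValueError as exc:
        raise QuantityParseError(text, str(exc)) from exc


def _fmt_num(v: float) -> str:
    return format(v, "g")


def format_quantity(q: Quantity) -> str:
    """Inverse of :func:`parse_quantity` on the printed grammar."""
    parts: list[str] = []
    if q.point is not None:
        parts.append(_fmt_num(q.point))
    if q.sd is not None:
        parts.append(f"± {_fmt_num(q.sd)}")
    if q.lo is not None and q.hi is not None:
        parts.append(f"({_fmt_num(q.lo)} − {_fmt_num(q.hi)})")
    elif q.hi is not None and q.point is not None:
        parts.append(f"(max {_fmt_num(q.hi)})")
    elif q.hi is not None:
        parts.append(f"max {_fmt_num(q.hi)}")
    return " ".join(parts)


@dataclass(frozen=True)
class CollapsePolicy:
    """Precedence for reducing a printed quantity to one number.

    The default — reported mean first, midpoint of the printed range next,
    the upper bound only when nothing else exists — mirrors how the source
    tables use averages whenever one was reported.  The rule actually applied
    is returned alongside the value so downstream outputs can record it.
    """

    order: tuple[str, ...] = ("point", "midpoint", "hi")

    _RULES = ("point", "midpoint", "hi")

    def __post_init__(self) -> None:
        if not self.order:
            raise ValueError("empty precedence list")
        for rule in self.order:
            if rule not in self._RULES:
                raise ValueError(f"unknown collapse rule {rule!r}")


DEFAULT_POLICY = CollapsePolicy()


def collapse(q: Quantity, policy: CollapsePolicy = DEFAULT_POLICY) -> tuple[float, str]:
    """Reduce ``q`` to a single value; returns ``(value, rule_used)``."""
    for rule in policy.order:
        if rule == "point" and q.point is not None:
            return q.point, "point"
        if rule == "midpoint" and q.lo is not None and q.hi is not None:
            return 0.5 * (q.lo + q.hi), "midpoint"
        if rule == "hi" and q.hi is not None:
            return q.hi, "hi-bound" if q.bound_only else "hi"
    raise ValueError(f"policy {policy.order} cannot collapse {q}")


# ---------------------------------------------------------------------------
# Organism records


_QUANTITY_FIELDS = ("B", "W", "U", "N", "L", "lam", "h", "n_w", "f", "ell", "d", "kappa")
_LENGTH_FIELDS = ("B", "W", "L", "lam", "h", "ell", "d")


@dataclass
class OrganismRecord:
    """One species-level row of the trait database.

    Geometry: body length ``B`` and width ``W``; flagellum/cilium count ``N``,
    length ``L``, wavelength ``lam``, amplitude (or helix radius) ``h``, wave
    count ``n_w``; cilium length ``ell``, spacing ``d`` and areal density
    ``kappa``.  Kinematics: swimming speed ``U`` and beat/rotation frequency
    ``f`` in cycles per second (models needing an angular rate multiply by
    2π themselves).
    """

    species: str
    group: str
    B: Quantity
    W: Quantity | None = None
    U: Quantity | None = None
    N: Quantity | None = None
    L: Quantity | None = None
    lam: Quantity | None = None
    h: Quantity | None = None
    n_w: Quantity | None = None
    f: Quantity | None = None
    ell: Quantity | None = None
    d: Quantity | None = None
    kappa: Quantity | None = None
    notes: str = ""
    refs: str = ""

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species must be non-empty")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {sorted(GROUPS)}")
        for name in _LENGTH_FIELDS:
            q = getattr(self, name)
            if q is None:
                continue
            for attr in ("point", "lo", "hi"):
                v = getattr(q, attr)
                if v is not None and v <= 0:
                    raise ValueError(f"{name} must be positive, got {attr}={v}")

    def validation_warnings(self) -> list[str]:
        w: list[str] = []
        for name in _QUANTITY_FIELDS:
            q = getattr(self, name)
            if q is not None:
                w.extend(f"{name}: {msg}" for msg in q.validation_warnings())
        if self.W is not None:
            try:
                bw = collapse(self.W)[0] / collapse(self.B)[0]
            except ValueError:
                bw = math.nan
            if bw > 1:
                w.append(f"aspect ratio W/B = {bw:.3g} > 1 (not prolate)")
        return w

    def get(self, name: str, policy: CollapsePolicy = DEFAULT_POLICY) -> tuple[float, str] | None:
        """Collapsed value of a quantity field, or None when absent."""
        q = getattr(self, name)
        if q is None:
            return None
        return collapse(q, policy)

    def to_dict(self) -> dict:
        d: dict = {"species": self.species, "group": self.group}
        for name in _QUANTITY_FIELDS:
            q = getattr(self, name)
            if q is not None:
                d[name] = q.to_dict()
        if self.notes:
            d["notes"] = self.notes
        if self.refs:
            d["refs"] = self.refs
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OrganismRecord":
        kw: dict = {"species": d["species"], "group": d["group"]}
        for name in _QUANTITY_FIELDS:
            if name in d and d[name] is not None:
                kw[name] = Quantity.from_dict(d[name])
        kw["notes"] = d.get("notes", "")
        kw["refs"] = d.get("refs", "")
        return cls(**kw)


_CSV_HEADER = ["species", "group", *_QUANTITY_FIELDS, "notes", "refs"]
_MANDATORY = ("species", "group", "B")


@dataclass
class RowDiagnostic:
    row: int
    species: str
    message: str
    fatal: bool


def _records_from_rows(
    rows: list[dict],
) -> tuple[list[OrganismRecord], list[RowDiagnostic]]:
    records: list[OrganismRecord] = []
    diags: list[RowDiagnostic] = []
    for i, row in enumerate(rows):
        species = (row.get("species") or "").strip()
        try:
            kw: dict = {"species": species, "group": (row.get("group") or "").strip()}
            for name in _QUANTITY_FIELDS:
                cell = row.get(name)
                if cell is None or not str(cell).strip():
                    continue
                kw[name] = parse_quantity(str(cell))
            kw["notes"] = (row.get("notes") or "").strip()
            kw["refs"] = (row.get("refs") or "").strip()
            if "B" not in kw:
                raise ValueError("missing mandatory B value")
            rec = OrganismRecord(**kw)
        except (ValueError, QuantityParseError) as exc:
            diags.append(RowDiagnostic(i, species, str(exc), fatal=True))
            continue
        for msg in rec.validation_warnings():
            diags.append(RowDiagnostic(i, species, msg, fatal=False))
        records.append(rec)
    return records, diags


def read_records(stream, fmt: str = "csv"):
    """Read organism records from a CSV or JSON stream or path.

    Returns ``(records, diagnostics)``: rows that fail validation become
    fatal diagnostics instead of records; soft warnings (e.g. an aspect
    ratio above 1) keep the record and add a non-fatal diagnostic.
    """
    close = False
    if isinstance(stream, (str,)) or hasattr(stream, "__fspath__"):
        stream = open(stream, "r", encoding="utf-8", newline="")
        close = True
    try:
        if fmt == "json":
            data = json.load(stream)
            rows = [d for d in data]
            records: list[OrganismRecord] = []
            diags: list[RowDiagnostic] = []
            for i, d in enumerate(rows):
                try:
                    rec = OrganismRecord.from_dict(d)
                except (KeyError, ValueError) as exc:
                    diags.append(RowDiagnostic(i, str(d.get("species", "")), str(exc), True))
                    continue
                for msg in rec.validation_warnings():
                    diags.append(RowDiagnostic(i, rec.species, msg, False))
                records.append(rec)
            return records, diags
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            return [], []
        missing = [c for c in _MANDATORY if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"missing mandatory columns: {', '.join(missing)}")
        unknown = [c for c in reader.fieldnames if c not in _CSV_HEADER]
        if unknown:
            raise ValueError(f"unknown columns: {', '.join(unknown)}")
        return _records_from_rows(list(reader))
    finally:
        if close:
            stream.close()


def write_records(records, stream, fmt: str = "csv") -> None:
    """Write records as CSV (cells in the printed grammar) or JSON."""
    close = False
    if isinstance(stream, (str,)) or hasattr(stream, "__fspath__"):
        stream = open(stream, "w", encoding="utf-8", newline="")
        close = True
    try:
        if fmt == "json":
            json.dump([r.to_dict() for r in records], stream, indent=1)
            stream.write("\n")
            return
        writer = csv.DictWriter(stream, fieldnames=_CSV_HEADER)
        writer.writeheader()
        for r in records:
            row = {"species": r.species, "group": r.group, "notes": r.notes, "refs": r.refs}
            for name in _QUANTITY_FIELDS:
                q = getattr(r, name)
                row[name] = format_quantity(q) if q is not None else ""
            writer.writerow(row)
    finally:
        if close:
            stream.close()
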