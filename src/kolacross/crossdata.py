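"""Data model, pedigree-label grammar, and file I/O for kola crossing trials.

A controlled-pollination trial is recorded as two tables:

* a *pollination* table with one row per cross x pollinator replicate
  (flowers pollinated, true pods set, pseudo-pods set, flowers dropped), and
* a *trait* table with pod/nut yield and quality measurements per cross.

Crosses are written in the field's pedigree notation, e.g. ``JX1/90 × JX1/51``
for a single hybrid cross between two genotypes, or
``B1/11 × B1/71 × B1/157 × B1/149`` for a double hybrid cross, i.e. a cross
between two F1 hybrid trees, each identified by its own parental pair.

The module also ships the two self-cross tables printed in full by the source
trial (field gene banks GX1 at Afosu and MX2 at Tafo) as packaged fixtures,
stored exactly as printed, one decimal place, never recomputed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, fields
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "GenotypeID",
    "CrossEntity",
    "CrossSpec",
    "CrossType",
    "PollinationRecord",
    "TraitRecord",
    "CrossDataset",
    "TRAIT_FIELDS",
    "POLLINATION_COLUMNS",
    "CrossParseError",
    "CrossClassificationError",
    "SchemaError",
    "RowParseError",
    "ValidationError",
    "parse_cross_label",
    "classify_cross_type",
    "read_cross_table",
    "write_pollination_csv",
    "write_trait_csv",
    "load_fixture",
    "FIXTURE_NAMES",
]


class CrossParseError(ValueError):
    """A cross label does not follow the 2- or 4-token pedigree grammar."""


class CrossClassificationError(ValueError):
    """A cross mixes entity kinds (genotype x hybrid-pair) and has no type."""


class SchemaError(ValueError):
    """An input table is missing required columns."""


class RowParseError(ValueError):
    """A cell in an input table could not be parsed; carries the row index."""


class ValidationError(ValueError):
    """A record violates a count or measurement invariant."""


def _norm_ws(text: str) -> str:
    """Collapse all (unicode) whitespace runs to single ASCII spaces."""
    return " ".join(text.split())


@dataclass(frozen=True)
class GenotypeID:
    """A genotype, identified by gene bank and accession (e.g. ``JX1/90``).

    MX2-style names carry no gene-bank prefix (``A1``, ``Club``, ``JB 32``);
    these parse with ``genebank=None`` and the whole token as accession.
    Embedded spaces inside an accession are preserved (single-spaced).
    """

    genebank: Optional[str]
    accession: str

    def __post_init__(self) -> None:
        if self.genebank is not None:
            object.__setattr__(self, "genebank", _norm_ws(self.genebank))
        object.__setattr__(self, "accession", _norm_ws(self.accession))
        if not self.accession or (self.genebank is not None and not self.genebank):
            raise CrossParseError(f"empty genotype identifier: {self!r}")

    @classmethod
    def parse(cls, token: str) -> "GenotypeID":
        token = _norm_ws(token)
        if not token:
            raise CrossParseError("empty genotype token")
        if "/" in token:
            genebank, accession = token.split("/", 1)
            return cls(genebank, accession)
        return cls(None, token)

    @property
    def label(self) -> str:
        return self.accession if self.genebank is None else f"{self.genebank}/{self.accession}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class CrossEntity:
    """One side of a cross: either a genotype or an F1 hybrid pair."""

    kind: str  # "genotype" | "hybrid-pair"
    members: tuple

    def __post_init__(self) -> None:
        if self.kind == "genotype":
            if len(self.members) != 1:
                raise CrossParseError("genotype entity needs exactly 1 member")
        elif self.kind == "hybrid-pair":
            if len(self.members) != 2:
                raise CrossParseError("hybrid-pair entity needs exactly 2 members")
        else:
            raise CrossParseError(f"unknown entity kind {self.kind!r}")

    @classmethod
    def genotype(cls, g: GenotypeID) -> "CrossEntity":
        return cls("genotype", (g,))

    @classmethod
    def hybrid(cls, a: GenotypeID, b: GenotypeID) -> "CrossEntity":
        return cls("hybrid-pair", (a, b))

    @property
    def label(self) -> str:
        return " × ".join(m.label for m in self.members)

    def unordered(self) -> frozenset:
        """Members as an unordered set; selfing direction is meaningless."""
        return frozenset(self.members)

    def same_as(self, other: "CrossEntity") -> bool:
        return self.kind == other.kind and self.unordered() == other.unordered()


# "×" with any spacing, or ASCII x/X with whitespace on both sides
_SEPARATOR = re.compile(r"\s*×\s*|\s+[xX]\s+")


def parse_cross_label(text: str) -> "CrossSpec":
    """Parse a pedigree cross label into a :class:`CrossSpec`.

    Two ID tokens give genotype × genotype; four give
    hybrid-pair(first two) × hybrid-pair(last two). ``×``, ``x`` and ``X``
    are all accepted as separators (the latter two need surrounding
    whitespace so they cannot be confused with letters inside a name).
    """
    cleaned = _norm_ws(text)
    if not cleaned:
        raise CrossParseError("empty cross label")
    tokens = _SEPARATOR.split(cleaned)
    if any(not t.strip() for t in tokens):
        raise CrossParseError(f"empty ID token in cross label {text!r}")
    ids = [GenotypeID.parse(t) for t in tokens]
    if len(ids) == 2:
        female, male = CrossEntity.genotype(ids[0]), CrossEntity.genotype(ids[1])
    elif len(ids) == 4:
        female = CrossEntity.hybrid(ids[0], ids[1])
        male = CrossEntity.hybrid(ids[2], ids[3])
    else:
        raise CrossParseError(
            f"cross label {text!r} has {len(ids)} ID tokens; expected 2 or 4"
        )
    return CrossSpec(female=female, male=male, label=text)


@dataclass(frozen=True)
class CrossSpec:
    """A parsed cross: female entity × male entity.

    Equality ignores the original label text, so any rendering that reparses
    to the same entities compares equal (label round-trip invariant).
    """

    female: CrossEntity
    male: CrossEntity
    label: str = field(compare=False, default="")

    @property
    def canonical_label(self) -> str:
        return f"{self.female.label} × {self.male.label}"

    @property
    def is_self(self) -> bool:
        return self.female.same_as(self.male)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_label


class CrossType(str, Enum):
    """Single/double × self/cross classification (SCS, SCC, DCS, DCC)."""

    SCS = "SCS"  # single hybrid self-cross (genotype selfed)
    SCC = "SCC"  # single hybrid cross (two different genotypes)
    DCS = "DCS"  # double hybrid self-cross (hybrid tree selfed)
    DCC = "DCC"  # double hybrid cross (two different hybrid trees)


def classify_cross_type(spec: CrossSpec) -> CrossType:
    """Classify a cross as SCS/SCC/DCS/DCC.

    Self-detection for double crosses compares unordered parental pairs.
    Mixed designs (genotype × hybrid-pair) are not part of the trial grammar
    and raise :class:`CrossClassificationError`.
    """
    if spec.female.kind != spec.male.kind:
        raise CrossClassificationError(
            f"mixed entity kinds in {spec.canonical_label!r}: "
            f"{spec.female.kind} × {spec.male.kind}"
        )
    if spec.female.kind == "genotype":
        return CrossType.SCS if spec.is_self else CrossType.SCC
    return CrossType.DCS if spec.is_self else CrossType.DCC


@dataclass(frozen=True)
class PollinationRecord:
    """Success/failure counts for one cross × pollinator replicate."""

    cross: CrossSpec
    replicate: int
    n_pollinated: int
    n_pod: int
    n_pseudo: int
    n_dropped: int
    row: Optional[int] = field(default=None, compare=False)
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        counts = (self.n_pollinated, self.n_pod, self.n_pseudo, self.n_dropped)
        if any(c < 0 for c in counts):
            raise ValidationError(
                f"negative count in {self.cross.canonical_label!r}"
                + (f" (row {self.row})" if self.row is not None else "")
            )
        if self.n_pod + self.n_pseudo + self.n_dropped > self.n_pollinated:
            raise ValidationError(
                f"n_pod + n_pseudo + n_dropped > n_pollinated for "
                f"{self.cross.canonical_label!r}"
                + (f" (row {self.row})" if self.row is not None else "")
            )


#: trait columns of the trait table, in reporting order
TRAIT_FIELDS = (
    "number_of_pods",
    "pod_weight",
    "pod_length",
    "pod_width",
    "nuts_per_pod",
    "nut_length",
    "nut_width",
    "weight_unpeeled",
    "weight_peeled",
    "outturn",
    "brix",
    "potential_alcohol",
    "firmness",
)

POLLINATION_COLUMNS = (
    "cross_label",
    "replicate",
    "n_pollinated",
    "n_pod",
    "n_pseudo",
    "n_dropped",
)


@dataclass(frozen=True)
class TraitRecord:
    """Pod and nut measurements for one cross (one replicate or table row).

    All measurements are optional (``None`` = not recorded). Weights in g,
    lengths in cm, outturn in %, brix in °Bx, potential alcohol in % v/v,
    firmness in lbf.
    """

    cross: CrossSpec
    number_of_pods: Optional[float] = None
    pod_weight: Optional[float] = None
    pod_length: Optional[float] = None
    pod_width: Optional[float] = None
    nuts_per_pod: Optional[float] = None
    nut_length: Optional[float] = None
    nut_width: Optional[float] = None
    weight_unpeeled: Optional[float] = None
    weight_peeled: Optional[float] = None
    outturn: Optional[float] = None
    brix: Optional[float] = None
    potential_alcohol: Optional[float] = None
    firmness: Optional[float] = None
    row: Optional[int] = field(default=None, compare=False)
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        where = f" (row {self.row})" if self.row is not None else ""
        for name in TRAIT_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(
                    f"negative {name} for {self.cross.canonical_label!r}{where}"
                )
        if self.outturn is not None and self.outturn > 100:
            raise ValidationError(
                f"outturn > 100% for {self.cross.canonical_label!r}{where}"
            )
        if (
            self.weight_peeled is not None
            and self.weight_unpeeled is not None
            and self.weight_peeled > self.weight_unpeeled
        ):
            raise ValidationError(
                f"weight_peeled > weight_unpeeled for "
                f"{self.cross.canonical_label!r}{where}"
            )

    def value(self, trait: str) -> Optional[float]:
        if trait not in TRAIT_FIELDS:
            raise KeyError(trait)
        return getattr(self, trait)


@dataclass
class CrossDataset:
    """A crossing-trial dataset: pollination records, trait records, metadata.

    ``aggregation`` declares how replicate counts combine into per-cross
    percentages: ``"pooled"`` (sum counts first; the default) or ``"mean"``
    (average replicate percentages). ``percentages`` optionally carries
    per-cross pod-set / pseudo-pod-set percentages for datasets (such as the
    printed fixtures) that report percentages without raw counts.
    """

    pollinations: list = field(default_factory=list)
    traits: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    aggregation: str = "pooled"
    percentages: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.aggregation not in ("pooled", "mean"):
            raise ValueError(f"unknown aggregation mode {self.aggregation!r}")

    # -- access ---------------------------------------------------------

    def cross_specs(self) -> dict:
        """All crosses in the dataset, keyed by canonical label."""
        out: dict = {}
        for rec in list(self.pollinations) + list(self.traits):
            out.setdefault(rec.cross.canonical_label, rec.cross)
        if self.percentages is not None:
            for lab in self.percentages.index:
                out.setdefault(lab, parse_cross_label(lab))
        return out

    def orphan_trait_crosses(self) -> list:
        """Trait crosses that have no pollination record (flagged, not fatal)."""
        if not self.pollinations:
            return []
        known = {r.cross.canonical_label for r in self.pollinations}
        return sorted(
            {t.cross.canonical_label for t in self.traits} - known
        )

    def pollination_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cross_label": r.cross.canonical_label,
                "replicate": r.replicate,
                "n_pollinated": r.n_pollinated,
                "n_pod": r.n_pod,
                "n_pseudo": r.n_pseudo,
                "n_dropped": r.n_dropped,
            }
            for r in self.pollinations
        ]
        return pd.DataFrame(rows, columns=list(POLLINATION_COLUMNS))

    def trait_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.traits:
            d = {"cross_label": r.cross.canonical_label}
            for name in TRAIT_FIELDS:
                d[name] = r.value(name)
            rows.append(d)
        return pd.DataFrame(rows, columns=["cross_label", *TRAIT_FIELDS])

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "metadata": self.metadata,
            "aggregation": self.aggregation,
            "pollinations": self.pollination_frame().to_dict(orient="records"),
            "traits": [
                {k: (None if pd.isna(v) else v) for k, v in row.items()}
                for row in self.trait_frame().to_dict(orient="records")
            ],
            "percentages": (
                None
                if self.percentages is None
                else self.percentages.reset_index()
                .rename(columns={"index": "cross_label"})
                .to_dict(orient="records")
            ),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _detect_sep(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cross_table(path, schema: str, sep: Optional[str] = None) -> CrossDataset:
    """Read a pollination or trait table (CSV/TSV) into a dataset fragment.

    ``schema`` is ``"pollination"`` or ``"trait"``. The delimiter is detected
    from the extension (``.tsv``/``.tab`` → tab) unless ``sep`` is given.
    Unknown extra columns are preserved per record in ``annotations``;
    1-based data row numbers are kept as parse provenance.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if schema == "pollination":
        required = list(POLLINATION_COLUMNS)
    elif schema == "trait":
        required = ["cross_label"]
    else:
        raise ValueError(f"unknown schema {schema!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )

    def _num(cell, row_idx, col, integer=False):
        if cell is None or (isinstance(cell, float) and pd.isna(cell)):
            return None
        text = str(cell).strip()
        if text == "" or text.upper() in ("NA", "NAN"):
            return None
        try:
            return int(text) if integer else float(text)
        except ValueError:
            raise RowParseError(
                f"{path.name} row {row_idx}: cannot parse {col}={text!r}"
            ) from None

    ds = CrossDataset(metadata={"source": str(path), "schema": schema})
    if schema == "pollination":
        extra = [c for c in df.columns if c not in POLLINATION_COLUMNS]
        for i, row in enumerate(df.itertuples(index=False), start=1):
            row = dict(zip(df.columns, row))
            spec = parse_cross_label(row["cross_label"])
            ds.pollinations.append(
                PollinationRecord(
                    cross=spec,
                    replicate=_num(row["replicate"], i, "replicate", integer=True),
                    n_pollinated=_num(row["n_pollinated"], i, "n_pollinated", True),
                    n_pod=_num(row["n_pod"], i, "n_pod", True),
                    n_pseudo=_num(row["n_pseudo"], i, "n_pseudo", True),
                    n_dropped=_num(row["n_dropped"], i, "n_dropped", True),
                    row=i,
                    annotations={c: row[c] for c in extra},
                )
            )
    else:
        trait_cols = [c for c in df.columns if c in TRAIT_FIELDS]
        extra = [c for c in df.columns if c != "cross_label" and c not in TRAIT_FIELDS]
        for i, row in enumerate(df.itertuples(index=False), start=1):
            row = dict(zip(df.columns, row))
            spec = parse_cross_label(row["cross_label"])
            values = {c: _num(row[c], i, c) for c in trait_cols}
            ds.traits.append(
                TraitRecord(
                    cross=spec,
                    row=i,
                    annotations={c: row[c] for c in extra},
                    **values,
                )
            )
    return ds


def write_pollination_csv(dataset: CrossDataset, path) -> None:
    dataset.pollination_frame().to_csv(path, index=False)


def write_trait_csv(dataset: CrossDataset, path) -> None:
    dataset.trait_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures: the two self-cross tables printed in full by the trial.
# Values are stored exactly as printed (one decimal); integrity is checked
# against column checksums shipped alongside the data.
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("gx1_self", "mx2_self")

_FIXTURE_META = {
    "gx1_self": {
        "genebank": "GX1",
        "site": "Afosu",
        "years": "2019-2020",
        "description": "pod set, yield and nut quality among GX1 self-crosses",
    },
    "mx2_self": {
        "genebank": "MX2",
        "site": "Tafo",
        "years": "2019-2020",
        "description": "pod set, yield and nut quality among MX2 self-crosses",
    },
}


def _fixture_text(filename: str) -> str:
    return resources.files("kolacross.data").joinpath(filename).read_text()


def load_fixture(name: str) -> CrossDataset:
    """Load a packaged self-cross table (``"gx1_self"`` or ``"mx2_self"``).

    Returns a dataset with one :class:`TraitRecord` per cross plus the printed
    per-cross pod-set / pseudo-pod-set percentages in ``percentages``.
    Raises ``KeyError`` for unknown names.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    import io

    df = pd.read_csv(io.StringIO(_fixture_text(f"{name}.csv")))
    checks = json.loads(_fixture_text("fixture_checksums.json"))[name]
    if len(df) != checks["n_rows"]:
        raise ValidationError(f"fixture {name}: expected {checks['n_rows']} rows")
    for col, expected in checks["column_sums"].items():
        got = round(float(df[col].sum()), 1)
        if got != expected:
            raise ValidationError(
                f"fixture {name}: column {col} sum {got} != expected {expected}"
            )

    ds = CrossDataset(metadata={"fixture": name, **_FIXTURE_META[name]})
    trait_cols = [c for c in df.columns if c in TRAIT_FIELDS]
    for i, row in df.iterrows():
        spec = parse_cross_label(row["cross_label"])
        ds.traits.append(
            TraitRecord(
                cross=spec,
                row=i + 1,
                **{c: float(row[c]) for c in trait_cols},
            )
        )
    pct = df.set_index("cross_label")[["pod_set_pct", "pseudo_pod_set_pct"]]
    pct.index = [parse_cross_label(l).canonical_label for l in pct.index]
    ds.percentages = pct
    return ds
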