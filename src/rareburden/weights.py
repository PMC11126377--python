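"""Per-variant weights from minor allele frequency and functional annotation.

Each qualifying variant receives two weights that are multiplied together:

* a MAF weight, a parabola in minor allele frequency with its vertex at the
  rarity cutoff, so that a variant at the cutoff (MAF = 0.01) gets weight 1
  and a variant with MAF approaching 0 gets weight 10::

      w(maf) = w_at_cap + (w_at_zero - w_at_cap) * (1 - maf / maf_cap)**2

* an annotation weight: a base weight for the variant's functional category
  (loss-of-function 100, nonsynonymous 5, ...) plus additive increments when
  PolyPhen calls a nonsynonymous variant possibly/probably damaging (+5/+10)
  or SIFT calls it deleterious (+20).

The numbers live in a :class:`WeightScheme`, which can be read from / written
to a plain-text config file so alternative weightings are a file edit away.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = [
    "CATEGORIES",
    "VariantAnnotation",
    "WeightScheme",
    "maf_weight",
    "annotation_weight",
    "combined_weight",
    "read_weight_scheme",
    "write_weight_scheme",
]

#: Functional categories in increasing order of nominal severity.
CATEGORIES = (
    "intronic_etc",
    "utr5",
    "synonymous",
    "splice_region",
    "utr3",
    "protein_altering",
    "inframe_indel",
    "lof",
)

_POLYPHEN_CLASSES = ("none", "possibly_damaging", "probably_damaging")
_SIFT_CLASSES = ("none", "deleterious")


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional annotation of one biallelic variant.

    PolyPhen and SIFT classify nonsynonymous (protein-altering) variants
    only; for every other category both must be ``"none"``.
    """

    category: str
    polyphen: str = "none"
    sift: str = "none"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown functional category {self.category!r}; "
                f"expected one of {', '.join(CATEGORIES)}"
            )
        if self.polyphen not in _POLYPHEN_CLASSES:
            raise ValueError(f"unknown PolyPhen class {self.polyphen!r}")
        if self.sift not in _SIFT_CLASSES:
            raise ValueError(f"unknown SIFT class {self.sift!r}")
        if self.category != "protein_altering" and (
            self.polyphen != "none" or self.sift != "none"
        ):
            raise ValueError(
                "PolyPhen/SIFT classes apply to protein_altering variants only "
                f"(got category={self.category!r})"
            )


def _default_base_weights() -> dict[str, float]:
    # LOF and nonsynonymous weights are the published ones; the remaining
    # categories default to stand-in values (see docs/methods.md) and are
    # overridable through the config file.
    return {
        "intronic_etc": 1.0,
        "utr5": 1.0,
        "synonymous": 1.0,
        "splice_region": 20.0,
        "utr3": 1.0,
        "protein_altering": 5.0,
        "inframe_indel": 10.0,
        "lof": 100.0,
    }


@dataclass(frozen=True)
class WeightScheme:
    """Parameters of the MAF parabola and the annotation weight table."""

    maf_cap: float = 0.01
    w_at_zero: float = 10.0
    w_at_cap: float = 1.0
    base_weights: dict[str, float] = field(default_factory=_default_base_weights)
    polyphen_increment: dict[str, float] = field(
        default_factory=lambda: {"possibly_damaging": 5.0, "probably_damaging": 10.0}
    )
    sift_increment: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.maf_cap <= 0.5:
            raise ValueError(f"maf_cap must be in (0, 0.5], got {self.maf_cap}")
        if self.w_at_zero <= self.w_at_cap:
            raise ValueError("w_at_zero must exceed w_at_cap")
        for cat, w in self.base_weights.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category in base_weights: {cat!r}")
            if w <= 0:
                raise ValueError(f"base weight for {cat!r} must be positive, got {w}")
        missing = set(CATEGORIES) - set(self.base_weights)
        if missing:
            raise ValueError(f"base_weights missing categories: {sorted(missing)}")


def maf_weight(maf: float, scheme: WeightScheme | None = None) -> float:
    """MAF weight: parabola through (0, 10) and (maf_cap, 1), vertex at the cap.

    Strictly decreasing on [0, maf_cap], hitting both endpoints exactly.
    """
    scheme = scheme or WeightScheme()
    if not 0 <= maf <= scheme.maf_cap:
        raise ValueError(
            f"MAF {maf} outside [0, {scheme.maf_cap}]; variants above the rarity "
            "cutoff must be filtered out before weighting"
        )
    rel = 1.0 - maf / scheme.maf_cap
    return scheme.w_at_cap + (scheme.w_at_zero - scheme.w_at_cap) * rel * rel


def annotation_weight(ann: VariantAnnotation, scheme: WeightScheme | None = None) -> float:
    """Base category weight plus PolyPhen/SIFT increments (additive)."""
    scheme = scheme or WeightScheme()
    try:
        w = scheme.base_weights[ann.category]
    except KeyError:
        raise ValueError(f"no base weight for category {ann.category!r}") from None
    if ann.polyphen != "none":
        w += scheme.polyphen_increment[ann.polyphen]
    if ann.sift == "deleterious":
        w += scheme.sift_increment
    return w


def combined_weight(
    maf: float, ann: VariantAnnotation, scheme: WeightScheme | None = None
) -> float:
    """Overall variant weight: MAF weight times annotation weight."""
    scheme = scheme or WeightScheme()
    return maf_weight(maf, scheme) * annotation_weight(ann, scheme)


# -- plain-text config round trip -------------------------------------------
#
# Format: one "key value" (or "key subkey value") pair per line, '#' comments.
#   maf_cap 0.01
#   w_at_zero 10
#   base lof 100
#   polyphen probably_damaging 10
#   sift deleterious 20


def write_weight_scheme(scheme: WeightScheme, path: str | Path) -> None:
    lines = [
        "# weighted burden scheme: MAF parabola and annotation weights",
        f"maf_cap {scheme.maf_cap:g}",
        f"w_at_zero {scheme.w_at_zero:g}",
        f"w_at_cap {scheme.w_at_cap:g}",
    ]
    for cat in CATEGORIES:
        lines.append(f"base {cat} {scheme.base_weights[cat]:g}")
    for cls in ("possibly_damaging", "probably_damaging"):
        lines.append(f"polyphen {cls} {scheme.polyphen_increment[cls]:g}")
    lines.append(f"sift deleterious {scheme.sift_increment:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_weight_scheme(path: str | Path) -> WeightScheme:
    scheme = WeightScheme()
    base = dict(scheme.base_weights)
    poly = dict(scheme.polyphen_increment)
    scalars: dict[str, float] = {}
    sift = scheme.sift_increment
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        try:
            if parts[0] in ("maf_cap", "w_at_zero", "w_at_cap") and len(parts) == 2:
                scalars[parts[0]] = float(parts[1])
            elif parts[0] == "base" and len(parts) == 3:
                base[parts[1]] = float(parts[2])
            elif parts[0] == "polyphen" and len(parts) == 3:
                poly[parts[1]] = float(parts[2])
            elif parts[0] == "sift" and len(parts) == 3 and parts[1] == "deleterious":
                sift = float(parts[2])
            else:
                raise ValueError
        except ValueError:
            raise ValueError(f"{path}:{lineno}: cannot parse weight line {raw!r}") from None
    return replace(
        WeightScheme(**scalars),
        base_weights=base,
        polyphen_increment=poly,
        sift_increment=sift,
    )
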