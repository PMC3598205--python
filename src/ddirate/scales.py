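"""Ordinal rating scales for drug-drug interaction severity.

Three five-category scales are bundled:

* ``DM`` — the decision model's action-oriented ratings A–E
  (no action / precautionary measures / clinical monitoring / avoid /
  contraindicated);
* ``pharmacologist`` — a clinical expert's conventional severity scale
  (no interaction / minor / moderate / major / contraindicated);
* ``MMX`` — Micromedex DrugDex categories
  (unknown / minor / moderate / major / contraindicated).

All scales are coded 1..5 in category order for statistical analysis.
``MMX`` "unknown" and the pharmacologist's "no interaction" occupy slot 1,
aligned with DM:A for cross-tabulation, but "unknown" means *missing
information*, not a safe combination; it therefore carries a missing flag
so downstream analyses can exclude those cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ScaleError(ValueError):
    """Unknown category label or incompatible scales."""


@dataclass(frozen=True)
class RatingScale:
    """An ordered categorical severity scale with numeric codes 1..k.

    Parameters
    ----------
    name:
        Scale identifier (e.g. ``"DM"``).
    categories:
        Category labels in increasing-severity order; code ``i+1`` is
        assigned to ``categories[i]``.
    missing_label:
        Optional label denoting "no rating available" rather than a
        severity judgement. It still occupies its positional slot in
        cross-tables but is flagged by :meth:`encode`.
    """

    name: str
    categories: tuple[str, ...]
    missing_label: str | None = None
    _lookup: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(set(c.lower() for c in self.categories)) != len(self.categories):
            raise ScaleError(f"scale {self.name!r}: duplicate category labels")
        if self.missing_label is not None and self.missing_label not in self.categories:
            raise ScaleError(
                f"scale {self.name!r}: missing_label {self.missing_label!r} "
                "is not one of the categories"
            )
        object.__setattr__(
            self, "_lookup", {c.lower(): i + 1 for i, c in enumerate(self.categories)}
        )

    def __len__(self) -> int:
        return len(self.categories)

    def encode(self, label: str) -> tuple[int, bool]:
        """Return ``(code, is_missing)`` for a category label.

        Labels are matched case-insensitively. ``is_missing`` is True only
        for the scale's ``missing_label``.
        """
        code = self._lookup.get(str(label).strip().lower())
        if code is None:
            raise ScaleError(
                f"unknown category {label!r} for scale {self.name!r}; "
                f"expected one of {list(self.categories)}"
            )
        return code, self.categories[code - 1] == self.missing_label

    def decode(self, code: int) -> str:
        """Canonical label for a numeric code 1..k."""
        if not 1 <= int(code) <= len(self.categories):
            raise ScaleError(f"code {code} out of range 1..{len(self.categories)}")
        return self.categories[int(code) - 1]

    def canonicalize(self, label: str) -> str:
        code, _ = self.encode(label)
        return self.decode(code)


def align(a: RatingScale, b: RatingScale) -> list[tuple[str, str]]:
    """Position-wise category correspondence between two scales.

    Used to label the axes of a cross-table: code ``i`` on scale ``a``
    corresponds to code ``i`` on scale ``b``.
    """
    if len(a) != len(b):
        raise ScaleError(
            f"cannot align scale {a.name!r} ({len(a)} categories) with "
            f"{b.name!r} ({len(b)} categories)"
        )
    return list(zip(a.categories, b.categories))


@dataclass(frozen=True)
class RatingRecord:
    """One rater's severity assignment for one drug-pair case."""

    case_id: str
    drug_a: str
    drug_b: str
    rater: str
    category: str


DM_SCALE = RatingScale("DM", ("A", "B", "C", "D", "E"))

PHARMACOLOGIST_SCALE = RatingScale(
    "pharmacologist",
    ("no interaction", "minor", "moderate", "major", "contraindicated"),
)

MMX_SCALE = RatingScale(
    "MMX",
    ("unknown", "minor", "moderate", "major", "contraindicated"),
    missing_label="unknown",
)

BUILTIN_SCALES: dict[str, RatingScale] = {
    s.name: s for s in (DM_SCALE, PHARMACOLOGIST_SCALE, MMX_SCALE)
}


def get_scale(name: str) -> RatingScale:
    try:
        return BUILTIN_SCALES[name]
    except KeyError:
        raise ScaleError(
            f"unknown scale {name!r}; built-in scales: {sorted(BUILTIN_SCALES)}"
        ) from None
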