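"""Intertemporal-choice item banks and the per-item indifference rate.

Every item offers a smaller immediate reward ``r`` against a larger reward
``R`` delivered after ``d`` days.  Under the hyperbolic discounting model
V(R, d) = R / (1 + K d), each item has a unique discount rate K* at which a
decision maker is exactly indifferent between the two options; an agent with
K > K* prefers the immediate reward.  The classic 27-item monetary choice
questionnaire (MCQ) ships here with its standard published amounts and
delays, partitioned into three delayed-reward magnitude bins of nine items.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ChoiceItem",
    "ItemBank",
    "implied_item_k",
    "kirby_mcq",
    "MAGNITUDE_BINS",
]

MAGNITUDE_BINS = ("small", "medium", "large")


class ItemValidationError(ValueError):
    """An item violates the choice-geometry invariants."""


@dataclass(frozen=True)
class ChoiceItem:
    """One fixed immediate-vs-delayed offer.

    Parameters
    ----------
    item_id : int
        Unique identifier within a bank.
    r_immediate : float
        Immediate reward amount (currency units, > 0).
    R_delayed : float
        Delayed reward amount; must exceed ``r_immediate``.
    delay_days : int
        Delay to the larger reward, in days (>= 1).
    magnitude_bin : str
        Delayed-reward magnitude category: ``small``, ``medium`` or ``large``.
    """

    item_id: int
    r_immediate: float
    R_delayed: float
    delay_days: int
    magnitude_bin: str = "small"

    def __post_init__(self) -> None:
        if not self.r_immediate > 0:
            raise ItemValidationError(
                f"r_immediate must be > 0, got {self.r_immediate}"
            )
        if not self.R_delayed > self.r_immediate:
            raise ItemValidationError(
                "R_delayed must exceed r_immediate, got "
                f"R_delayed={self.R_delayed}, r_immediate={self.r_immediate}"
            )
        if not self.delay_days >= 1:
            raise ItemValidationError(
                f"delay_days must be >= 1, got {self.delay_days}"
            )
        if self.magnitude_bin not in MAGNITUDE_BINS:
            raise ItemValidationError(
                f"magnitude_bin must be one of {MAGNITUDE_BINS}, "
                f"got {self.magnitude_bin!r}"
            )


@dataclass(frozen=True)
class ItemBank:
    """An ordered, immutable collection of :class:`ChoiceItem`."""

    name: str
    items: tuple[ChoiceItem, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ItemValidationError(f"duplicate item_ids in bank {self.name!r}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def subset(self, magnitude_bin: str) -> "ItemBank":
        """Items of one magnitude bin, original order preserved."""
        if magnitude_bin not in MAGNITUDE_BINS:
            raise ItemValidationError(f"unknown magnitude bin {magnitude_bin!r}")
        return ItemBank(
            name=f"{self.name}:{magnitude_bin}",
            items=tuple(
                it for it in self.items if it.magnitude_bin == magnitude_bin
            ),
        )


def implied_item_k(item: ChoiceItem) -> float:
    """Discount rate at which the item's two options have equal value.

    Setting r = R / (1 + K d) and solving for K gives

        K* = (R - r) / (r * d).

    A deterministic hyperbolic discounter with rate K chooses the immediate
    reward exactly when K > K*.

    Returns
    -------
    float
        The item's indifference discount rate (1/day), always > 0.
    """
    return (item.R_delayed - item.r_immediate) / (
        item.r_immediate * item.delay_days
    )


# Standard 27-item monetary choice questionnaire: (id, r, R, d, bin).
# Delayed-reward magnitudes: small 25-35, medium 50-60, large 75-85.
_KIRBY_ITEMS = (
    (1, 54, 55, 117, "medium"),
    (2, 55, 75, 61, "large"),
    (3, 19, 25, 53, "small"),
    (4, 31, 85, 7, "large"),
    (5, 14, 25, 19, "small"),
    (6, 47, 50, 160, "medium"),
    (7, 15, 35, 13, "small"),
    (8, 25, 60, 14, "medium"),
    (9, 78, 80, 162, "large"),
    (10, 40, 55, 62, "medium"),
    (11, 11, 30, 7, "small"),
    (12, 67, 75, 119, "large"),
    (13, 34, 35, 186, "small"),
    (14, 27, 50, 21, "medium"),
    (15, 69, 85, 91, "large"),
    (16, 49, 60, 89, "medium"),
    (17, 80, 85, 157, "large"),
    (18, 24, 35, 29, "small"),
    (19, 33, 80, 14, "large"),
    (20, 28, 30, 179, "small"),
    (21, 34, 50, 30, "medium"),
    (22, 25, 30, 80, "small"),
    (23, 41, 75, 20, "large"),
    (24, 54, 60, 111, "medium"),
    (25, 54, 80, 30, "large"),
    (26, 22, 25, 136, "small"),
    (27, 20, 55, 7, "medium"),
)


def kirby_mcq() -> ItemBank:
    """The classic 27-item MCQ bank (9 items per magnitude bin).

    Amounts are unitless currency (the instrument's published dollar values,
    administered in euro/CHF-equivalents); delays are days.
    """
    return ItemBank(
        name="kirby_mcq_27",
        items=tuple(
            ChoiceItem(
                item_id=i,
                r_immediate=float(r),
                R_delayed=float(R),
                delay_days=int(d),
                magnitude_bin=b,
            )
            for i, r, R, d, b in _KIRBY_ITEMS
        ),
    )
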