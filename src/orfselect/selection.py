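"""Ampicillin ORF-selection simulator on labelled clone populations.

Selection is modelled as binary survival per clone class: clones whose
insert translates through to the downstream reporter fragment survive,
stop-containing (off-frame) clones do not. Two refinements mirror the
bench observations:

* *frame-correction leak* — a small fraction of off-frame clones carry 1–2
  bp deletions in the 5' adapter that shift the insert into frame, so they
  survive selection even though sequencing with the nominal adapter calls
  them off-frame;
* an optional plating dilution thinning all classes equally.

With initial open fraction q, leak rate λ and otherwise perfect selection,
the expected post-selection open fraction (leak clones scored off-frame, as
re-sequencing with fresh adapters would score them) is q / (q + (1 − q)·λ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

CLASSES = ("native_in_frame", "open_non_native", "off_frame", "leak_corrected")
OPEN_CLASSES = ("native_in_frame", "open_non_native")


@dataclass(frozen=True)
class ClonePopulation:
    """Clone counts by frame class."""

    native_in_frame: int = 0
    open_non_native: int = 0
    off_frame: int = 0
    leak_corrected: int = 0

    def __post_init__(self) -> None:
        for name in CLASSES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")

    @property
    def total(self) -> int:
        return sum(getattr(self, name) for name in CLASSES)

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in CLASSES}

    def open_fraction(self, leak_as_open: bool = False) -> float:
        """Fraction of clones scored in-frame.

        ``leak_as_open=True`` is the sequencing-with-original-adapters view,
        where a frame-corrected clone reads as in-frame; the default scores
        leak clones off-frame (the adapter-resynthesis / re-amplification
        view).
        """
        if self.total == 0:
            return float("nan")
        n_open = sum(getattr(self, name) for name in OPEN_CLASSES)
        if leak_as_open:
            n_open += self.leak_corrected
        return n_open / self.total


@dataclass(frozen=True)
class SelectionModel:
    """Per-class survival probabilities, leak rate and plating dilution."""

    survival: dict[str, float] = field(
        default_factory=lambda: {
            "native_in_frame": 1.0,
            "open_non_native": 1.0,
            "off_frame": 0.0,
            "leak_corrected": 1.0,
        }
    )
    leak_rate: float = 0.10
    plating_dilution: float = 1.0

    def __post_init__(self) -> None:
        for name in CLASSES:
            p = self.survival.get(name)
            if p is None or not 0.0 <= p <= 1.0:
                raise ValueError(f"survival[{name!r}] must be a probability")
        if not 0.0 <= self.leak_rate <= 1.0:
            raise ValueError("leak_rate must be in [0, 1]")
        if self.plating_dilution < 1.0:
            raise ValueError("plating_dilution must be >= 1")


@dataclass(frozen=True)
class EnrichmentReport:
    pre: ClonePopulation
    post: ClonePopulation
    pre_open_fraction: float
    post_open_fraction: float
    post_open_fraction_leak_as_open: float
    fold_decrease: float
    enrichment_factor: float

    def as_dict(self) -> dict:
        return {
            "pre": self.pre.as_dict(),
            "post": self.post.as_dict(),
            "pre_open_fraction": self.pre_open_fraction,
            "post_open_fraction": self.post_open_fraction,
            "post_open_fraction_leak_as_open": self.post_open_fraction_leak_as_open,
            "fold_decrease": self.fold_decrease,
            "enrichment_factor": self.enrichment_factor,
        }


def apply_selection(
    pop: ClonePopulation,
    model: SelectionModel = SelectionModel(),
    seed: Optional[int | np.random.Generator] = None,
) -> tuple[ClonePopulation, EnrichmentReport]:
    """Draw the surviving population under the selection model.

    Off-frame clones first convert to the leak-corrected class with
    probability ``leak_rate`` (adapter deletion restoring the frame), then
    every class survives binomially at its survival probability, after an
    optional uniform plating dilution. Deterministic under ``seed``.
    """
    if pop.total == 0:
        raise ValueError("cannot select from an empty population")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_leak = int(rng.binomial(pop.off_frame, model.leak_rate)) if pop.off_frame else 0
    pre = replace(
        pop,
        off_frame=pop.off_frame - n_leak,
        leak_corrected=pop.leak_corrected + n_leak,
    )

    survivors = {}
    for name in CLASSES:
        n = getattr(pre, name)
        p = model.survival[name] / model.plating_dilution
        survivors[name] = int(rng.binomial(n, p)) if n else 0
    post = ClonePopulation(**survivors)

    pre_q = pop.open_fraction()
    post_q = post.open_fraction()
    report = EnrichmentReport(
        pre=pop,
        post=post,
        pre_open_fraction=pre_q,
        post_open_fraction=post_q,
        post_open_fraction_leak_as_open=post.open_fraction(leak_as_open=True),
        fold_decrease=pop.total / post.total if post.total else float("inf"),
        enrichment_factor=post_q / pre_q if pre_q else float("inf"),
    )
    return post, report


def expected_postselection_open_fraction(q: float, leak_rate: float) -> float:
    """Closed-form post-selection open fraction under perfect selection.

    Survivors are the open clones (mass q) plus the leaked off-frame clones
    (mass (1 − q)·λ); scoring leak clones off-frame gives
    q / (q + (1 − q)·λ).
    """
    denom = q + (1.0 - q) * leak_rate
    return q / denom if denom else float("nan")


def sample_colonies(
    pop: ClonePopulation,
    n: int,
    seed: Optional[int | np.random.Generator] = None,
    replace_: bool = True,
) -> dict[str, int]:
    """Draw ``n`` colonies for PCR-style screening.

    Multinomial by class proportions (with replacement by default; set
    ``replace_=False`` for exact without-replacement sampling, which
    requires n ≤ total).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = pop.total
    if total == 0:
        raise ValueError("cannot sample from an empty population")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.array([getattr(pop, name) for name in CLASSES], dtype=float)
    if replace_:
        draw = rng.multinomial(n, counts / counts.sum())
    else:
        if n > total:
            raise ValueError("cannot sample more colonies than clones without replacement")
        draw = rng.multivariate_hypergeometric(counts.astype(np.int64), n)
    return dict(zip(CLASSES, (int(x) for x in draw)))


__all__ = [
    "CLASSES",
    "ClonePopulation",
    "EnrichmentReport",
    "SelectionModel",
    "apply_selection",
    "expected_postselection_open_fraction",
    "sample_colonies",
]
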