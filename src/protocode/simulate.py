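"""Stochastic two-step encoding of codons: the memory-bank simulation.

The model's central claim is that codon→amino-acid assignments were not
decreed but *learned*: anticodon–codon pairing first creates a repertoire
of uncoded ("white") codons — a blank tape — and repeated deliveries of
amino acids by charged tRNAs then write each codon's identity into a
per-codon frequency memory until the assignment is fixed ("blue").  The
genetic code is the converged state of this memory bank, accumulated over
three stages.

A stage run is a sequence of cycles.  Each cycle draws one stage sense
codon uniformly at random, charges its cognate tRNA (optionally with a
mischarge probability), and records the delivered amino acid in the bank.
A codon becomes *encoded* once it has at least ``min_observations``
deliveries and its modal amino acid holds at least a
``modal_fraction_threshold`` share of them; the encoded state is
monotone — it never reverts — and the run ends when every sense codon of
the stage is encoded or ``max_cycles`` is exhausted (reported as an
unconverged result, not an exception).

At the universal-code stage the three stop codons enter the repertoire
but never receive deliveries: they are the relics of anticodon–codon
pairing without amino-acid input, and they end every run uncoded.

With no mischarges and ``min_observations = 1`` a stage run is exactly a
coupon-collector process over its sense codons; for 4 GNC codons the
expected number of cycles to convergence is 4·(1 + 1/2 + 1/3 + 1/4) ≈ 8.33.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .pairing import TRNA, anticodon_for_codon, charge_trna
from .tables import STOP_LETTERS, Stage, stage_table

__all__ = [
    "UNCODED",
    "ENCODED",
    "StageOrderError",
    "MemoryBank",
    "SimConfig",
    "EncodingTrace",
    "start_cycle",
    "run_stage",
    "recovered_code",
    "run_all_stages",
]

logger = logging.getLogger(__name__)

UNCODED = "uncoded"
ENCODED = "encoded"


class StageOrderError(ValueError):
    """Stages must be chained in order from a converged predecessor."""


@dataclass
class MemoryBank:
    """Per-codon frequency counts of delivered amino acids plus the
    uncoded/encoded state — white vs. blue circles.

    ``counts[codon][aa]`` is the number of deliveries of *aa* to *codon*;
    their grand total always equals the number of delivery events
    simulated.  ``first_seen[codon][aa]`` records the global event index
    of the first such delivery, used to break modal ties deterministically
    in :func:`recovered_code`.  Stop codons appear in ``state`` (always
    uncoded) but never in ``counts``.
    """

    stage: Stage
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    state: dict[str, str] = field(default_factory=dict)
    first_seen: dict[str, dict[str, int]] = field(default_factory=dict)
    n_events: int = 0

    @property
    def sense_codons(self) -> list[str]:
        return [c for c in self.state if c not in STOP_LETTERS]

    @property
    def n_encoded(self) -> int:
        return sum(1 for c, s in self.state.items() if s == ENCODED)

    @property
    def converged(self) -> bool:
        """All sense codons encoded (stops are exempt: they stay white)."""
        return all(
            s == ENCODED for c, s in self.state.items() if c not in STOP_LETTERS
        )

    def white_codons(self) -> list[str]:
        return [c for c, s in self.state.items() if s == UNCODED]

    def record(self, codon: str, amino_acid: str) -> None:
        if codon in STOP_LETTERS:
            raise ValueError(f"stop codon {codon} cannot receive deliveries")
        self.n_events += 1
        c = self.counts.setdefault(codon, {})
        c[amino_acid] = c.get(amino_acid, 0) + 1
        self.first_seen.setdefault(codon, {}).setdefault(
            amino_acid, self.n_events
        )


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one stage run.

    Parameters
    ----------
    stage
        Code stage to run.
    max_cycles
        Cycle budget before the run is reported unconverged.
    error_rate
        Mischarge probability per delivery, in [0, 0.5) — above one half
        the modal amino acid is no longer guaranteed to be the cognate
        one even in the limit.
    min_observations
        Deliveries a codon needs before it can be declared encoded
        (1 suits noiseless runs; ~25 gives a comfortable majority-vote
        margin at 10% mischarge).
    modal_fraction_threshold
        Minimum share of the codon's deliveries its modal amino acid must
        hold, in (0.5, 1].
    seed
        Seed for the single random source driving codon draws and
        charging.
    """

    stage: Stage
    max_cycles: int = 100_000
    error_rate: float = 0.0
    min_observations: int = 1
    modal_fraction_threshold: float = 0.95
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage", Stage.coerce(self.stage))
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(f"error_rate must be in [0, 0.5), got {self.error_rate}")
        if not 0.5 < self.modal_fraction_threshold <= 1.0:
            raise ValueError(
                "modal_fraction_threshold must be in (0.5, 1], got "
                f"{self.modal_fraction_threshold}"
            )
        if self.min_observations < 1:
            raise ValueError("min_observations must be >= 1")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


@dataclass
class EncodingTrace:
    """Event log and white/blue bookkeeping of one stage run.

    ``events`` holds (cycle, codon, delivered amino acid, mischarge flag)
    tuples.  ``snapshots`` is compact — one (cycle, encoded, uncoded)
    entry per cycle — while ``initial_state`` and ``final_state`` keep the
    full white/blue maps at cycle 0 and at the end of the run.
    """

    stage: Stage
    events: list[tuple[int, str, str, bool]] = field(default_factory=list)
    snapshots: list[dict[str, int]] = field(default_factory=list)
    initial_state: dict[str, str] = field(default_factory=dict)
    final_state: dict[str, str] = field(default_factory=dict)
    converged: bool = False
    cycles: int = 0
    mischarges: int = 0
    residual_white: tuple[str, ...] = ()


def start_cycle(stage: Stage | str, previous: Optional[MemoryBank] = None) -> MemoryBank:
    """Open a stage: carry forward the previous stage's encoded codons and
    add this stage's new codons as uncoded with zero counts.

    The first stage takes ``previous=None``; later stages require a
    *converged* bank of the immediately preceding stage.
    """
    stage = Stage.coerce(stage)
    bank = MemoryBank(stage=stage)
    if stage.previous is None:
        if previous is not None:
            raise StageOrderError(f"stage {stage.value} takes no previous bank")
    else:
        if previous is None:
            raise StageOrderError(
                f"stage {stage.value} requires a converged {stage.previous.value} bank"
            )
        if previous.stage is not stage.previous:
            raise StageOrderError(
                f"stage {stage.value} must follow {stage.previous.value}, "
                f"got a {previous.stage.value} bank"
            )
        if not previous.converged:
            raise StageOrderError(
                f"previous {previous.stage.value} bank has not converged "
                f"(white: {previous.white_codons()})"
            )
        for codon, st in previous.state.items():
            bank.state[codon] = st
            if codon in previous.counts:
                bank.counts[codon] = dict(previous.counts[codon])
                bank.first_seen[codon] = dict(previous.first_seen[codon])
        bank.n_events = previous.n_events
    table = stage_table(stage)
    for codon in table.assignments:
        bank.state.setdefault(codon, UNCODED)
    return bank


def _is_encoded(bank: MemoryBank, codon: str, config: SimConfig) -> bool:
    counts = bank.counts.get(codon)
    if not counts:
        return False
    total = sum(counts.values())
    if total < config.min_observations:
        return False
    return max(counts.values()) / total >= config.modal_fraction_threshold


def run_stage(
    config: SimConfig,
    previous: Optional[MemoryBank] = None,
    record_events: bool = True,
) -> tuple[MemoryBank, EncodingTrace]:
    """Run one stage of the encoding simulation to convergence (or to the
    cycle budget), returning the bank and its trace.

    Each cycle draws one sense codon uniformly (encoded codons keep
    receiving deliveries, harmlessly), charges its cognate tRNA via
    :func:`protocode.pairing.charge_trna` with the configured mischarge
    rate, and records the delivery.  Fully reproducible given the seed.
    Non-convergence is reported on the trace (``converged=False`` with
    the residual white set), never raised.
    """
    bank = start_cycle(config.stage, previous)
    trace = EncodingTrace(stage=config.stage, initial_state=dict(bank.state))
    rng = np.random.default_rng(config.seed)
    table = stage_table(config.stage)
    sense = sorted(table.sense)
    # uncharged tRNA per sense codon, reused across cycles
    trnas = {
        c: TRNA(anticodon=anticodon_for_codon(c), stage_class="pre-tRNA"
                if config.stage is Stage.GNC else "tRNA")
        for c in sense
    }
    pending = {c for c in sense if bank.state[c] != ENCODED}
    n_sense = len(sense)
    cycle = 0
    while pending and cycle < config.max_cycles:
        cycle += 1
        codon = sense[rng.integers(n_sense)]
        charged = charge_trna(trnas[codon], config.stage, config.error_rate, rng)
        bank.record(codon, charged.charged_amino_acid)
        if charged.mischarged:
            trace.mischarges += 1
        if codon in pending and _is_encoded(bank, codon, config):
            bank.state[codon] = ENCODED
            pending.discard(codon)
        if record_events:
            trace.events.append(
                (cycle, codon, charged.charged_amino_acid, charged.mischarged)
            )
            trace.snapshots.append(
                {
                    "cycle": cycle,
                    "encoded": n_sense - len(pending),
                    "uncoded": len(pending),
                }
            )
    trace.cycles = cycle
    trace.converged = not pending
    trace.final_state = dict(bank.state)
    trace.residual_white = tuple(sorted(pending))
    logger.info(
        "stage %s: %s after %d cycles (%d mischarges, %d/%d codons encoded)",
        config.stage.value,
        "converged" if trace.converged else "NOT converged",
        cycle,
        trace.mischarges,
        n_sense - len(pending),
        n_sense,
    )
    return bank, trace


def recovered_code(bank: MemoryBank) -> dict[str, str]:
    """The code the bank has learned: each codon with at least one
    observation mapped to its modal amino acid.

    Ties are broken toward the earliest-observed amino acid and logged;
    codons with zero observations are excluded, not guessed.
    """
    recovered: dict[str, str] = {}
    for codon in sorted(bank.counts):
        counts = bank.counts[codon]
        if not counts:
            continue
        top = max(counts.values())
        modal = [aa for aa, n in counts.items() if n == top]
        if len(modal) > 1:
            logger.info(
                "codon %s: modal tie among %s at %d observations; "
                "keeping earliest-observed",
                codon, sorted(modal), top,
            )
        recovered[codon] = min(modal, key=lambda aa: bank.first_seen[codon][aa])
    return recovered


def run_all_stages(
    configs: Sequence[SimConfig],
    record_events: bool = True,
) -> tuple[MemoryBank, list[EncodingTrace]]:
    """Chain the three stage runs GNC → SNS → UG, carrying the memory
    bank forward; on full convergence the final bank has 61 encoded sense
    codons covering 20 amino acids."""
    expected = [Stage.GNC, Stage.SNS, Stage.UG]
    if [c.stage for c in configs] != expected:
        raise StageOrderError(
            "configs must cover stages GNC, SNS, UG in order; got "
            f"{[c.stage.value for c in configs]}"
        )
    bank: Optional[MemoryBank] = None
    traces: list[EncodingTrace] = []
    for config in configs:
        bank, trace = run_stage(config, bank, record_events=record_events)
        traces.append(trace)
        if not trace.converged:
            break
    assert bank is not None
    return bank, traces
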