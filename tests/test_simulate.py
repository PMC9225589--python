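"""Memory-bank encoding simulation: white→blue convergence and recovery."""

import numpy as np
import pytest

from protocode.simulate import (
    ENCODED,
    UNCODED,
    MemoryBank,
    SimConfig,
    StageOrderError,
    recovered_code,
    run_all_stages,
    run_stage,
    start_cycle,
)
from protocode.tables import STOP_LETTERS, Stage, stage_table


def noiseless_configs(seeds=(1, 2, 3)):
    return [
        SimConfig(stage=s, seed=seed)
        for s, seed in zip((Stage.GNC, Stage.SNS, Stage.UG), seeds)
    ]


def converged_bank(stage: Stage, seed: int = 1) -> MemoryBank:
    bank = None
    for s, cfg in zip(Stage, noiseless_configs((seed, seed + 1, seed + 2))):
        bank, trace = run_stage(cfg, bank)
        assert trace.converged
        if s is stage:
            return bank
    raise AssertionError


def test_start_cycle_white_blue_counts():
    gnc = start_cycle(Stage.GNC)
    assert (len(gnc.white_codons()), gnc.n_encoded) == (4, 0)
    sns = start_cycle(Stage.SNS, converged_bank(Stage.GNC))
    assert (len(sns.white_codons()), sns.n_encoded) == (12, 4)
    ug = start_cycle(Stage.UG, converged_bank(Stage.SNS))
    # 45 new sense codons white, plus the 3 stops which also start (and
    # stay) white
    white = set(ug.white_codons())
    assert ug.n_encoded == 16
    assert len(white - set(STOP_LETTERS)) == 45
    assert set(STOP_LETTERS) <= white


def test_stage_order_is_enforced():
    with pytest.raises(StageOrderError):
        start_cycle(Stage.SNS)  # missing previous bank
    with pytest.raises(StageOrderError):
        start_cycle(Stage.UG, converged_bank(Stage.GNC))  # skips SNS
    unconverged = start_cycle(Stage.GNC)
    with pytest.raises(StageOrderError):
        start_cycle(Stage.SNS, unconverged)
    with pytest.raises(StageOrderError):
        start_cycle(Stage.GNC, converged_bank(Stage.GNC))


def test_noiseless_stage_recovers_the_table_exactly():
    bank, trace = run_stage(SimConfig(stage=Stage.GNC, seed=99))
    assert trace.converged
    assert recovered_code(bank) == dict(stage_table(Stage.GNC).sense)


def test_event_conservation_and_snapshots():
    bank, trace = run_stage(SimConfig(stage=Stage.GNC, seed=5))
    assert bank.n_events == len(trace.events) == trace.cycles
    total = sum(sum(c.values()) for c in bank.counts.values())
    assert total == bank.n_events
    assert all(s == UNCODED for s in trace.initial_state.values())
    assert all(s == ENCODED for s in trace.final_state.values())
    # snapshots are per-cycle and the encoded count is monotone
    assert [s["cycle"] for s in trace.snapshots] == list(range(1, trace.cycles + 1))
    encoded = [s["encoded"] for s in trace.snapshots]
    assert encoded == sorted(encoded)
    assert encoded[-1] == 4


def test_encoded_state_is_monotone_across_stages():
    bank = None
    seen_encoded: set[str] = set()
    for cfg in noiseless_configs():
        bank, trace = run_stage(cfg, bank)
        now_encoded = {c for c, s in bank.state.items() if s == ENCODED}
        assert seen_encoded <= now_encoded
        seen_encoded = now_encoded


def test_chained_noiseless_run_reaches_the_universal_code():
    bank, traces = run_all_stages(noiseless_configs())
    assert [t.converged for t in traces] == [True, True, True]
    assert bank.n_encoded == 61
    recovered = recovered_code(bank)
    assert recovered == dict(stage_table(Stage.UG).sense)
    assert len(set(recovered.values())) == 20
    # per-stage newly encoded counts 4, 12, 45
    deltas = [
        sum(1 for c, s in t.initial_state.items()
            if s == UNCODED and c not in STOP_LETTERS)
        for t in traces
    ]
    assert deltas == [4, 12, 45]


def test_stop_codons_never_accumulate_observations():
    bank, traces = run_all_stages(noiseless_configs())
    for stop in STOP_LETTERS:
        assert stop not in bank.counts
        assert bank.state[stop] == UNCODED
    drawn = {event[1] for trace in traces for event in trace.events}
    assert drawn.isdisjoint(STOP_LETTERS)


def test_same_seeds_give_identical_traces():
    a = run_all_stages(noiseless_configs())[1]
    b = run_all_stages(noiseless_configs())[1]
    assert [t.events for t in a] == [t.events for t in b]
    assert [t.final_state for t in a] == [t.final_state for t in b]


def test_non_convergence_is_reported_not_raised():
    bank, trace = run_stage(SimConfig(stage=Stage.GNC, max_cycles=2, seed=0))
    assert not trace.converged
    assert trace.cycles == 2
    assert trace.residual_white
    assert set(trace.residual_white) <= set(stage_table(Stage.GNC).sense)


def test_gnc_convergence_follows_the_coupon_collector_mean():
    """Noiseless GNC encoding is a coupon-collector process over 4 codons:
    the mean cycles to convergence is 4*(1 + 1/2 + 1/3 + 1/4) = 25/3,
    checked within 3 standard errors over seeded runs."""
    cycles = [
        run_stage(SimConfig(stage=Stage.GNC, seed=s), record_events=False)[1].cycles
        for s in range(1000)
    ]
    mean = np.mean(cycles)
    se = np.std(cycles, ddof=1) / np.sqrt(len(cycles))
    assert abs(mean - 25 / 3) < 3 * se


def test_noisy_majority_vote_still_recovers_the_tables():
    """With 10% mischarge, 25 minimum observations and a 0.6 modal
    threshold, the recovered mapping equals the stage table."""
    bank = None
    for i, stage in enumerate(Stage):
        cfg = SimConfig(
            stage=stage, seed=100 + i, error_rate=0.1,
            min_observations=25, modal_fraction_threshold=0.6,
        )
        bank, trace = run_stage(cfg, bank, record_events=False)
        assert trace.converged
        assert trace.mischarges > 0
        recovered = recovered_code(bank)
        assert recovered == dict(stage_table(stage).sense)


def test_recovered_code_edge_cases():
    empty = MemoryBank(stage=Stage.GNC)
    assert recovered_code(empty) == {}
    # modal tie broken toward the earliest-observed amino acid
    bank = MemoryBank(stage=Stage.GNC)
    bank.record("GGC", "G")
    bank.record("GGC", "A")
    assert recovered_code(bank) == {"GGC": "G"}
    bank.record("GGC", "A")
    assert recovered_code(bank) == {"GGC": "A"}


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(stage=Stage.GNC, error_rate=0.5)
    with pytest.raises(ValueError):
        SimConfig(stage=Stage.GNC, modal_fraction_threshold=0.5)
    with pytest.raises(ValueError):
        SimConfig(stage=Stage.GNC, min_observations=0)
    with pytest.raises(StageOrderError):
        run_all_stages([SimConfig(stage=Stage.GNC)])
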