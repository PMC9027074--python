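"""Unit and property tests of the shift-register neuron core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmdasim import (
    AMPA_DEFAULT,
    GABA_DEFAULT,
    NMDA_DEFAULT,
    NeuronConfig,
    RegisterBank,
    SynapseState,
    WaveformParams,
    calcium_power,
    ltp_step,
    memory_multiplier,
    poisson_train,
    simulate,
    waveform_kernel,
    waveform_value,
)
from nmdasim.config import DT_MS


# ----------------------------------------------------------------------
# waveform

@pytest.mark.parametrize(
    "params,t,expected",
    [
        (AMPA_DEFAULT, 1.0, 0.0),       # still inside the synaptic delay
        (AMPA_DEFAULT, 3.0, 5.0),       # rise endpoint = peak
        (GABA_DEFAULT, 3.0, -2.5),      # inhibitory peak
        (AMPA_DEFAULT, 16.0, 0.0),      # decay endpoint back at zero
        (AMPA_DEFAULT, 2.0, 2.5),       # halfway up the rise
        (AMPA_DEFAULT, 9.5, 5.0 / 13.0 * 6.5),  # decay branch value
    ],
)
def test_waveform_piecewise_values(params, t, expected):
    assert waveform_value(params, t) == pytest.approx(expected, abs=1e-12)


def test_waveform_peak_equals_a_max_at_rise_end():
    for params in (AMPA_DEFAULT, NMDA_DEFAULT, GABA_DEFAULT):
        grid = np.arange(0, params.support_ms + 5, 0.5)
        vals = [waveform_value(params, t) for t in grid]
        extremum = max(vals, key=abs)
        assert extremum == pytest.approx(params.a_max)
        assert waveform_value(params, params.t_sd + params.t_r) == pytest.approx(params.a_max)


@given(t=st.floats(min_value=0, max_value=100, allow_nan=False))
@settings(deadline=None, derandomize=True)
def test_waveform_zero_outside_support(t):
    params = AMPA_DEFAULT
    v = waveform_value(params, t)
    if t <= params.t_sd or t > params.support_ms:
        assert v == 0.0
    else:
        assert 0.0 <= v <= params.a_max


def test_waveform_rejects_nonfinite_time():
    with pytest.raises(ValueError):
        waveform_value(AMPA_DEFAULT, math.nan)


def test_waveform_param_invariants_enforced():
    with pytest.raises(ValueError):
        WaveformParams(-1.0, 1, 2, 13, "AMPA")  # excitatory must depolarize
    with pytest.raises(ValueError):
        WaveformParams(2.0, 1, 2, 10, "GABA")   # inhibitory must hyperpolarize
    with pytest.raises(ValueError):
        WaveformParams(5.0, 1, 0.0, 13, "AMPA")


# ----------------------------------------------------------------------
# registers

def _bank_series(config, deliveries, n_steps):
    """Run a bank standalone: deliveries = {step: [(input_id, weight)]}."""
    bank = RegisterBank(config)
    out = np.empty(n_steps)
    for i in range(n_steps):
        for iid, wgt in deliveries.get(i, []):
            bank.deliver_spike(iid, wgt)
        out[i] = bank.advance_and_sum()
    return out


def test_fresh_bank_rests_at_rep():
    cfg = NeuronConfig(duration_ms=100)
    assert np.allclose(_bank_series(cfg, {}, 50), cfg.ReP)


def test_single_excitatory_delivery_matches_sampled_kernels():
    cfg = NeuronConfig(duration_ms=100)
    n = 40
    s = _bank_series(cfg, {0: [("exc0", 1.0)]}, n)
    ka = waveform_kernel(cfg.ampa)
    kn = waveform_kernel(cfg.nmda)
    expected = np.full(n, cfg.ReP)
    expected[: len(ka)] += ka
    expected[: len(kn)] += kn
    assert np.allclose(s, expected)
    # peak of the pair: ReP + 5 (AMPA) + 1 (NMDA) at t_sd + t_r = 3 ms
    assert s[6] == pytest.approx(cfg.ReP + 6.0)


def test_isolated_ampa_peak_reaches_minus_75():
    # shrink the NMDA contribution to isolate the AMPA register
    cfg = NeuronConfig(
        duration_ms=100, nmda=WaveformParams(1e-12, 1.0, 2.0, 13.0, "NMDA")
    )
    s = _bank_series(cfg, {0: [("exc0", 1.0)]}, 40)
    assert s.max() == pytest.approx(-75.0)


def test_simultaneous_excitation_and_inhibition_sum_linearly():
    cfg = NeuronConfig(
        duration_ms=100, nmda=WaveformParams(1e-12, 1.0, 2.0, 13.0, "NMDA")
    )
    s = _bank_series(cfg, {0: [("exc0", 1.0), ("inh0", 1.0)]}, 40)
    # AMPA +5 and GABA −2.5 peak together at 3 ms -> −77.5
    assert s[6] == pytest.approx(-77.5)


def test_register_superposition_equals_bruteforce_sum():
    """Multiple spikes with arbitrary weights superpose linearly: the bank
    output equals the brute-force sum of shifted, scaled waveforms."""
    cfg = NeuronConfig(duration_ms=200)
    deliveries = {
        0: [("exc0", 1.0)],
        1: [("exc0", 2.0)],
        3: [("exc1", 1.5), ("inh0", 1.0)],
        9: [("exc0", 1.0)],
    }
    n = 80
    s = _bank_series(cfg, deliveries, n)

    expected = np.full(n, cfg.ReP)
    kernels = {
        "exc0": [waveform_kernel(cfg.ampa), waveform_kernel(cfg.nmda)],
        "exc1": [waveform_kernel(cfg.ampa), waveform_kernel(cfg.nmda)],
        "inh0": [waveform_kernel(cfg.gaba)],
    }
    for step, events in deliveries.items():
        for iid, wgt in events:
            for k in kernels[iid]:
                hi = min(n, step + len(k))
                expected[step:hi] += wgt * k[: hi - step]
    assert np.allclose(s, expected)


def test_double_weight_doubles_deflection():
    cfg = NeuronConfig(duration_ms=100)
    s1 = _bank_series(cfg, {0: [("exc0", 1.0)]}, 40) - cfg.ReP
    s2 = _bank_series(cfg, {0: [("exc0", 2.0)]}, 40) - cfg.ReP
    assert np.allclose(s2, 2 * s1)


def test_unknown_input_rejected():
    bank = RegisterBank(NeuronConfig(duration_ms=10))
    with pytest.raises(KeyError):
        bank.deliver_spike("exc99", 1.0)


# ----------------------------------------------------------------------
# plasticity

def test_memory_multiplier_reference_points():
    assert memory_multiplier(0.0) == 1.0
    assert memory_multiplier(999_999.0) == pytest.approx(2.0, abs=1e-3)
    assert memory_multiplier(9.0) == pytest.approx(1.1667, abs=1e-4)


def test_memory_multiplier_increasing_and_concave():
    c = np.linspace(0, 1e5, 200)
    m = np.array([memory_multiplier(v) for v in c])
    assert np.all(np.diff(m) > 0)
    assert np.all(np.diff(np.diff(m)) < 1e-12)
    with pytest.raises(ValueError):
        memory_multiplier(-1.0)


def test_calcium_power_linear_and_clamped(caplog):
    assert calcium_power(-80.0, 9.0, -80.0) == 0.0
    assert calcium_power(-68.0, 9.0, -80.0) == pytest.approx(108.0)
    assert calcium_power(-68.0, 135.0, -80.0) == pytest.approx(1620.0)
    with caplog.at_level("WARNING", logger="nmdasim"):
        assert calcium_power(-90.0, 9.0, -80.0) == 0.0
    assert "clamped" in caplog.text


def test_ltp_step_gating_and_forgetting():
    cfg = NeuronConfig(duration_ms=100)
    state = SynapseState(C=100.0, M=memory_multiplier(100.0))

    # gate closed (S below −68): spike does not induce, C only decays
    closed = ltp_step(state, -70.0, True, cfg)
    assert closed.C == pytest.approx(100.0 * cfg.forgetting_coefficient)

    # gate open: C strictly increases
    opened = ltp_step(state, -60.0, True, cfg)
    assert opened.C > state.C
    assert opened.M == pytest.approx(memory_multiplier(opened.C))

    # prolonged silence: geometric decay to zero, M back to 1
    s = state
    for _ in range(20000):
        s = ltp_step(s, cfg.ReP, False, cfg)
    assert s.C == pytest.approx(0.0, abs=1e-3)
    assert s.M == pytest.approx(1.0, abs=1e-4)


def test_gate_correctness_extreme_thresholds(short_protocol):
    never = simulate(
        NeuronConfig(duration_ms=2000, Ca_threshold=math.inf), short_protocol
    )
    assert never.C.max() == 0.0
    always = simulate(
        NeuronConfig(duration_ms=2000, Ca_threshold=-math.inf), short_protocol
    )
    # with the gate forced open, C increases at every spike arriving on a
    # depolarized membrane and never at non-spike steps beyond decay
    assert always.C.max() > 0.0
    steps = short_protocol.trains["exc0"].steps
    c0 = always.C[0]
    depolarized = steps[(steps > 0) & (always.S[steps] > always.config.ReP)]
    assert np.all(c0[depolarized] > c0[depolarized - 1])


# ----------------------------------------------------------------------
# full simulation

def test_zero_stimulus_rests_silently():
    trace = simulate(NeuronConfig(duration_ms=500), {})
    assert np.all(trace.S == -80.0)
    assert trace.n_spikes == 0
    assert trace.LTP == 1.0
    assert trace.LTP_time_ms == 0.0


def test_empty_duration_rejected():
    with pytest.raises(ValueError):
        NeuronConfig(duration_ms=0.0)


def test_simulation_is_deterministic(short_config, short_protocol):
    a = simulate(short_config, short_protocol)
    b = simulate(short_config, short_protocol)
    assert np.array_equal(a.S, b.S)
    assert np.array_equal(a.spikes, b.spikes)
    assert np.array_equal(a.C, b.C)
    assert a.summary() == b.summary()


def test_spike_count_nondecreasing_in_input_rate():
    cfg = NeuronConfig(duration_ms=4000)
    counts = []
    for rate in (2.0, 5.0, 10.0, 20.0, 40.0):
        trains = {
            f"exc{i}": poisson_train(
                rate, 4000, np.random.SeedSequence(entropy=9, spawn_key=(i,)), f"exc{i}"
            )
            for i in range(3)
        }
        counts.append(simulate(cfg, trains).n_spikes)
    assert counts == sorted(counts)
    assert counts[-1] > 0


def test_refractory_limits_spike_count(short_protocol):
    trace = simulate(NeuronConfig(duration_ms=2000), short_protocol)
    n_steps = trace.config.duration_steps
    assert trace.n_spikes <= n_steps / trace.config.refractory_steps
    # no two output spikes closer than the refractory period
    spike_steps = np.flatnonzero(trace.spikes)
    if spike_steps.size > 1:
        assert np.diff(spike_steps).min() > trace.config.refractory_steps


def test_weight_multiplier_bounds_hold_throughout(short_config, short_protocol):
    trace = simulate(short_config, short_protocol)
    c_max = trace.C.max()
    upper = 1.0 + math.log(c_max + 1.0) / (6.0 * short_config.clog)
    assert trace.M.min() >= 1.0
    assert trace.M.max() <= upper + 1e-12
    assert trace.LTP >= 1.0


def test_raising_unblock_threshold_never_increases_calcium_load():
    """Virtual memantine: a higher Mg2+-unblock threshold can only remove
    induction events, so the accumulated calcium drive is non-increasing
    in the threshold at fixed protocol and seed."""
    from nmdasim import default_protocol

    prot = default_protocol(6000, seed=3)
    for power in (9.0, 63.0, 135.0):
        loads = [
            simulate(
                NeuronConfig(
                    duration_ms=6000, power_coefficient=power, Ca_threshold=th
                ),
                prot,
            ).ca_accum
            for th in (-68.0, -65.0, -63.0, -55.0)
        ]
        assert all(a >= b for a, b in zip(loads, loads[1:]))


def test_trace_dataframe_round_trip(tmp_path, short_config, short_protocol):
    trace = simulate(short_config, short_protocol)
    df = trace.to_dataframe()
    assert list(df.columns[:4]) == ["step", "time_ms", "S_mV", "spike"]
    assert {"C_exc0", "M_exc0", "C_exc2", "M_exc2"} <= set(df.columns)
    path = tmp_path / "trace.csv"
    trace.to_csv(str(path))
    assert path.read_text().startswith("step,time_ms,S_mV,spike")
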