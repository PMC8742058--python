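import math

import numpy as np
import pytest

from qmarkush.circuit import Circuit
from qmarkush.noise import (
    FAMILIES,
    CouplingGraph,
    DensityMatrix,
    NoiseModel,
    apply_readout_error,
    depolarizing_channel,
    error_scaling_experiment,
    load_coupling_graph,
    load_noise_model,
    noisy_probabilities,
    routing_cost,
    simulate_noisy,
    synthetic_vigo_like_model,
    thermal_relaxation_channel,
    vigo_coupling,
)


def random_density_matrix(rng: np.random.Generator, n_qubits: int) -> DensityMatrix:
    dim = 2**n_qubits
    a = rng.normal(size=(dim, dim)) + 1j * rng.normal(size=(dim, dim))
    rho = a @ a.conj().T
    return DensityMatrix(rho / np.trace(rho), n_qubits)


class TestDepolarizing:
    def test_p_zero_is_identity(self):
        rng = np.random.default_rng(0)
        rho = random_density_matrix(rng, 2)
        out = depolarizing_channel(rho, 0.0, [0])
        assert np.allclose(out.matrix, rho.matrix)

    def test_p_one_fully_mixes_the_qubit(self):
        rho = DensityMatrix.zero(1)
        out = depolarizing_channel(rho, 1.0, [0])
        assert np.allclose(out.matrix, np.eye(2) / 2)

    def test_two_qubit_full_depolarization(self):
        rho = DensityMatrix.zero(2)
        out = depolarizing_channel(rho, 1.0, [0, 1])
        assert np.allclose(out.matrix, np.eye(4) / 4)

    @pytest.mark.parametrize("seed", range(20))
    def test_cptp_on_random_states(self, seed):
        rng = np.random.default_rng(seed)
        rho = random_density_matrix(rng, 3)
        out = depolarizing_channel(rho, float(rng.uniform(0, 1)),
                                   [int(rng.integers(3))])
        out.validate(atol=1e-9)


class TestThermalRelaxation:
    def test_zero_duration_is_identity(self):
        rho = random_density_matrix(np.random.default_rng(1), 1)
        out = thermal_relaxation_channel(rho, 100.0, 80.0, 0.0, 0)
        assert np.allclose(out.matrix, rho.matrix)

    def test_long_duration_relaxes_to_ground(self):
        rho = DensityMatrix(np.array([[0, 0], [0, 1]], dtype=complex), 1)
        out = thermal_relaxation_channel(rho, 10.0, 10.0, 1e6, 0)
        assert np.allclose(out.matrix, [[1, 0], [0, 0]], atol=1e-12)

    def test_plus_state_coherence_decay_closed_form(self):
        # |+><+| after t = T2: off-diagonal magnitude e^{-1} / 2
        plus = np.full((2, 2), 0.5, dtype=complex)
        t2 = 50.0
        out = thermal_relaxation_channel(DensityMatrix(plus, 1), 100.0, t2, t2, 0)
        assert abs(abs(out.matrix[0, 1]) - math.exp(-1) / 2) < 1e-9

    def test_unphysical_times_rejected(self):
        rho = DensityMatrix.zero(1)
        with pytest.raises(ValueError, match="T2"):
            thermal_relaxation_channel(rho, 10.0, 25.0, 1.0, 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_cptp_on_random_states(self, seed):
        rng = np.random.default_rng(100 + seed)
        rho = random_density_matrix(rng, 2)
        out = thermal_relaxation_channel(rho, 50.0, 60.0,
                                         float(rng.uniform(0, 100)),
                                         int(rng.integers(2)))
        out.validate(atol=1e-9)


class TestReadoutError:
    def test_zero_flips_is_identity(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        eye = np.eye(2)
        assert np.allclose(apply_readout_error(p, eye), p)

    def test_certain_flips_complement_the_distribution(self):
        p = np.array([0.7, 0.1, 0.15, 0.05])
        flip = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = apply_readout_error(p, flip)
        assert np.allclose(out, p[::-1])

    def test_probability_conserved(self):
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(8))
        m = np.array([[0.95, 0.05], [0.1, 0.9]])
        out = apply_readout_error(p, [m, m, m])
        assert abs(out.sum() - 1.0) < 1e-12
        assert (out >= 0).all()

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            apply_readout_error(np.array([0.5, 0.5]), np.array([[0.9, 0.2], [0.1, 0.9]]))


class TestSimulateNoisy:
    def test_noiseless_model_reproduces_ideal(self, two_qubit_comparison_circuit):
        probs = noisy_probabilities(two_qubit_comparison_circuit, NoiseModel(),
                                    measure_qubits=[0, 1])
        assert np.allclose(probs, [1, 0, 0, 0], atol=1e-9)

    def test_depolarization_strictly_shrinks_the_target(self, two_qubit_comparison_circuit):
        noisy = NoiseModel(p_depol_1q=0.002, p_depol_2q=0.02)
        probs = noisy_probabilities(two_qubit_comparison_circuit, noisy,
                                    measure_qubits=[0, 1])
        assert probs[0] < 1.0 - 1e-6

    def test_fixed_seed_reproducible(self, two_qubit_comparison_circuit):
        noise = synthetic_vigo_like_model()
        a = simulate_noisy(two_qubit_comparison_circuit, noise, shots=200, seed=7)
        b = simulate_noisy(two_qubit_comparison_circuit, noise, shots=200, seed=7)
        assert a == b
        assert sum(a.values()) == 200

    def test_register_cap(self):
        with pytest.raises(ValueError, match="density"):
            noisy_probabilities(Circuit(8), NoiseModel())


class TestErrorScalingExperiment:
    def test_zero_noise_gives_full_correctness(self, two_qubit_comparison_circuit):
        df = error_scaling_experiment(two_qubit_comparison_circuit, NoiseModel(),
                                      "depolarizing", {"00"}, shots=256,
                                      repeats=3, seed=0, measure_qubits=[0, 1])
        assert (df["mean_correct"] == 1.0).all()

    @pytest.mark.parametrize("family", FAMILIES)
    def test_correctness_monotone_in_error_scale(self, family,
                                                 two_qubit_comparison_circuit):
        noise = synthetic_vigo_like_model()
        df = error_scaling_experiment(two_qubit_comparison_circuit, noise,
                                      family, {"00"}, shots=1024, repeats=10,
                                      seed=2, measure_qubits=[0, 1])
        means = df.sort_values("factor")["mean_correct"].tolist()
        assert means[0] >= means[1] >= means[2]

    def test_depolarizing_halving_helps_most(self, two_qubit_comparison_circuit):
        # in the synthetic model the per-gate depolarizing error dominates
        noise = synthetic_vigo_like_model()
        gains = {}
        for family in FAMILIES:
            df = error_scaling_experiment(two_qubit_comparison_circuit, noise,
                                          family, {"00"}, shots=1024,
                                          repeats=10, seed=3,
                                          measure_qubits=[0, 1])
            df = df.set_index("factor")
            gains[family] = df.loc[0.5, "mean_correct"] - df.loc[1.0, "mean_correct"]
        assert max(gains, key=gains.get) == "depolarizing"

    def test_unknown_family_rejected(self, two_qubit_comparison_circuit):
        with pytest.raises(ValueError, match="family"):
            error_scaling_experiment(two_qubit_comparison_circuit, NoiseModel(),
                                     "cosmic", {"00"})


class TestRoutingCost:
    def test_adjacent_cnot_costs_nothing(self):
        c = Circuit(2)
        c.add("cx", 0, 1)
        assert routing_cost(c, vigo_coupling(), {0: 0, 1: 1}) == 0

    def test_fully_connected_graph_costs_nothing(self, two_qubit_comparison_circuit):
        nodes = tuple(range(4))
        edges = tuple((a, b) for a in nodes for b in nodes if a < b)
        full = CouplingGraph(nodes=nodes, edges=edges)
        mapping = {q: q for q in range(4)}
        assert routing_cost(two_qubit_comparison_circuit, full, mapping) == 0

    def test_t_shaped_mapping_beats_linear(self, two_qubit_comparison_circuit):
        coupling = vigo_coupling()
        t_shaped = {0: 1, 1: 2, 2: 0, 3: 3}
        linear = {0: 4, 1: 3, 2: 1, 3: 0}
        cost_t = routing_cost(two_qubit_comparison_circuit, coupling, t_shaped)
        cost_l = routing_cost(two_qubit_comparison_circuit, coupling, linear)
        assert cost_t <= cost_l

    def test_non_injective_mapping_rejected(self):
        c = Circuit(2)
        c.add("cx", 0, 1)
        with pytest.raises(ValueError, match="injective"):
            routing_cost(c, vigo_coupling(), {0: 1, 1: 1})

    def test_disconnected_endpoints_rejected(self):
        c = Circuit(2)
        c.add("cx", 0, 1)
        g = CouplingGraph(nodes=(0, 1, 2), edges=((1, 2),))
        with pytest.raises(ValueError, match="disconnected"):
            routing_cost(c, g, {0: 0, 1: 2})


class TestConfigFiles:
    def test_noise_model_yaml(self, tmp_path):
        path = tmp_path / "noise.yaml"
        path.write_text(
            "t1: 50000\nt2: 70000\np_depol_1q: 0.001\np_depol_2q: 0.01\n"
            "readout: [0.02, 0.03]\ngate_durations: {1q: 35, cx: 300}\n"
            "scale: {thermal: 1.0}\n"
        )
        nm = load_noise_model(str(path))
        assert nm.t1 == 50000 and nm.readout == (0.02, 0.03)

    def test_unphysical_config_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("t1: 10\nt2: 25\n")
        with pytest.raises(ValueError, match="T2"):
            load_noise_model(str(path))

    def test_coupling_edge_list(self, tmp_path):
        path = tmp_path / "graph.txt"
        path.write_text("# T-shaped\n0 1\n1 2\n1 3\n3 4\n")
        g = load_coupling_graph(str(path))
        assert g == vigo_coupling()
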