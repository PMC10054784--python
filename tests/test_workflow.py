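import numpy as np
import pandas as pd
import pytest

from dp4stereo import reference
from dp4stereo.data_model import config_id
from dp4stereo.synthetic import (
    SyntheticSpec,
    candidate_for,
    dp4_parameters_for,
    generate_truth,
    generate_wrong_candidates,
)
from dp4stereo.workflow import (
    StereoScanResult,
    WorkflowConfig,
    enumerate_combinations,
    enumerate_single_flips,
    run_full_workflow,
    select_principle_centers,
    single_flip_scan,
)


@pytest.mark.parametrize("n,expected", [(22, 22), (1, 1), (0, 0)])
def test_single_flip_counts(n, expected):
    flips = enumerate_single_flips((0,) * n)
    assert len(flips) == expected
    base = (0,) * n
    for cfg in flips:
        assert sum(a != b for a, b in zip(cfg, base)) == 1


def test_single_flips_follow_declared_center_order():
    flips = enumerate_single_flips((0, 1, 0))
    assert flips == [(1, 1, 0), (0, 0, 0), (0, 1, 1)]


@pytest.mark.parametrize("m,expected", [(6, 64), (0, 1), (2, 4)])
def test_combination_counts(m, expected):
    combos = enumerate_combinations((0,) * 10, list(range(m)))
    assert len(combos) == expected
    assert combos[0] == (0,) * 10  # base included first
    assert len(set(combos)) == len(combos)  # no duplicates


def test_combination_guard_and_duplicates():
    with pytest.raises(ValueError, match="guard"):
        enumerate_combinations((0,) * 25, list(range(21)))
    with pytest.raises(ValueError, match="duplicate"):
        enumerate_combinations((0, 0), [0, 0])


def _synthetic_scan(deviations, delta_g=None, centers=None):
    """Build a scan table directly from per-center CMAE deviations."""
    centers = centers or [f"SC{i+1}" for i in range(len(deviations))]
    base_cmae_h, base_cmae_c = 0.10, 1.2
    rows = [
        {"center": "(base)", "candidate_id": "0" * len(centers),
         "delta_g": float("nan"), "evaluable": True,
         "CMAE_1H": base_cmae_h, "CMAE_13C": base_cmae_c}
    ]
    for i, (c, dev) in enumerate(zip(centers, deviations)):
        cfg = [0] * len(centers)
        cfg[i] = 1
        rows.append(
            {"center": c, "candidate_id": config_id(cfg),
             "delta_g": float("nan") if delta_g is None else delta_g[i],
             "evaluable": True,
             "CMAE_1H": base_cmae_h + dev * 0.1, "CMAE_13C": base_cmae_c + dev}
        )
    return StereoScanResult(pd.DataFrame(rows), "0" * len(centers), tuple(centers))


def test_select_separates_constructed_low_deviation_centers():
    scan = _synthetic_scan([0.01, 1.0, 0.02, 1.2, 1.1])
    sel = select_principle_centers(scan, max_m=6)
    assert set(sel.centers) == {"SC1", "SC3"}


def test_select_requires_positive_max_m():
    scan = _synthetic_scan([0.1, 0.2])
    with pytest.raises(ValueError):
        select_principle_centers(scan, max_m=0)


def test_select_reproduces_staged_narrowing_scenario():
    """22 centers: 6 principle centers survive after one NOESY exclusion and
    three energy exclusions, mirroring the published selection."""
    principle = list(reference.PRINCIPLE_CENTERS)
    noesy = list(reference.NOESY_EXCLUDED)
    energy = list(reference.ENERGY_EXCLUDED)
    others = [f"C-x{i}" for i in range(22 - len(principle) - len(noesy) - len(energy))]
    centers = principle + noesy + energy + others
    rng = np.random.default_rng(12)
    dev = []
    dg = []
    for c in centers:
        if c in principle or c in noesy:
            dev.append(rng.uniform(0.0, 0.05))
            dg.append(rng.uniform(0, 5))
        elif c in energy:
            dev.append(rng.uniform(0.0, 0.05))  # low deviation but high energy
            dg.append(rng.uniform(32, 50))
        else:
            dev.append(rng.uniform(1.0, 2.0))
            dg.append(rng.uniform(0, 5))
    scan = _synthetic_scan(dev, delta_g=dg, centers=centers)
    sel = select_principle_centers(
        scan,
        max_m=6,
        exclusions={noesy[0]: "NOESY: missing H-10'/H-19''' correlation"},
        energy_window=30.0,
    )
    assert set(sel.centers) == set(principle)
    assert len(sel.centers) == 6
    assert set(sel.excluded) == set(noesy + energy)
    assert len(enumerate_combinations((0,) * 22, [centers.index(c) for c in sel.centers])) == 64


def test_threshold_selecting_zero_centers_errors():
    scan = _synthetic_scan([5.0, 5.1, 5.2])
    with pytest.raises(ValueError, match="relax"):
        select_principle_centers(scan, threshold_sd=0.0)


@pytest.fixture(scope="module")
def three_center_run():
    spec = SyntheticSpec(n_centers=3, seed=7)
    system = generate_truth(spec)
    base = spec.resolved_configuration
    cands = generate_wrong_candidates(
        system, enumerate_combinations(base, [0, 1, 2])
    )
    config = WorkflowConfig(
        sigma_reference=dict(system.record.sigma_reference),
        threshold_sd=None,
        max_m=3,
    )
    report = run_full_workflow(
        system.nuclei, system.stereocenters, cands,
        dp4_parameters_for(spec), config,
    )
    return system, cands, config, report


def test_workflow_recovers_true_configuration(three_center_run):
    system, _, _, report = three_center_run
    assert report["ranking"][0]["candidate_id"] == system.record.true_candidate_id
    assert report["n_combinatorial_candidates"] == 8
    assert report["not_evaluable"] == []


def test_workflow_ranking_invariant_to_candidate_order(three_center_run):
    system, cands, config, report = three_center_run
    spec = system.spec
    shuffled = dict(reversed(list(cands.items())))
    report2 = run_full_workflow(
        system.nuclei, system.stereocenters, shuffled,
        dp4_parameters_for(spec), config,
    )
    assert report2["ranking"] == report["ranking"]


def test_missing_candidate_listed_not_evaluable(three_center_run):
    system, cands, config, _ = three_center_run
    partial = {k: v for k, v in cands.items() if k != "011"}
    report = run_full_workflow(
        system.nuclei, system.stereocenters, partial,
        dp4_parameters_for(system.spec), config,
    )
    assert report["not_evaluable"] == ["011"]
    assert len(report["ranking"]) == 7


def test_identical_candidate_tables_tie_flagged():
    spec = SyntheticSpec(n_centers=2, seed=19)
    system = generate_truth(spec)
    truth = candidate_for(system, (0, 0))
    # two distinct ids, byte-identical shieldings
    from dp4stereo.data_model import CandidateStructure

    cands = {
        "00": truth,
        "10": CandidateStructure("10", (1, 0), truth.conformers),
        "01": candidate_for(system, (0, 1)),
        "11": candidate_for(system, (1, 1)),
    }
    config = WorkflowConfig(
        sigma_reference=dict(system.record.sigma_reference),
        threshold_sd=None, max_m=2,
    )
    report = run_full_workflow(
        system.nuclei, system.stereocenters, cands,
        dp4_parameters_for(spec), config,
    )
    top_two = report["ranking"][:2]
    assert {r["candidate_id"] for r in top_two} == {"00", "10"}
    assert all(r["tied"] for r in top_two)


def test_concentrated_perturbation_ranks_that_flip_last():
    """The flip whose offsets are concentrated on many nuclei at 2x the
    noise scale lands last in the single-flip CMAE scan ordering."""
    import dataclasses

    seed_spec = SyntheticSpec(n_centers=3, seed=23)
    labels = [n.label for n in generate_truth(seed_spec).nuclei if not n.exchangeable]
    spec = dataclasses.replace(
        seed_spec,
        perturb_multiplier=2.0,
        locality_map={0: labels[:3], 1: labels[:18], 2: labels[-3:]},
    )
    system = generate_truth(spec)
    base = spec.resolved_configuration
    cands = generate_wrong_candidates(system, [base] + enumerate_single_flips(base))
    config = WorkflowConfig(sigma_reference=dict(system.record.sigma_reference))
    scan = single_flip_scan(system.nuclei, system.stereocenters, cands, config)
    sel = select_principle_centers(scan, max_m=3, threshold_sd=None)
    dev = sel.deviations.set_index("center")["deviation"]
    assert dev.idxmax() == "SC2"
    t = scan.table.set_index("center")
    assert t.loc["SC2", "CMAE_1H"] > t.loc["(base)", "CMAE_1H"]
    assert t.loc["SC2", "CMAE_13C"] > t.loc["(base)", "CMAE_13C"]
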