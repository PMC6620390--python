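"""Scene generator: determinism, ground-truth invariants, fixtures."""

import numpy as np
import pytest
from scipy import stats as sps

from sasmorph.pipeline import pooled_analysis, stack_seeds
from sasmorph.synthetic import (ScenarioConfig, generate_scene, read_fixture,
                                write_fixture)
from sasmorph.volume import SYNAPSE


def test_identical_seed_gives_bit_identical_scenes(small_config):
    vol1, truth1 = generate_scene(small_config)
    vol2, truth2 = generate_scene(small_config)
    assert np.array_equal(vol1.labels, vol2.labels)
    assert [vars(s) for s in truth1.synapses] == \
        [vars(s) for s in truth2.synapses]


def test_zero_density_scene_has_dendrites_only():
    cfg = ScenarioConfig(volume_shape=(256, 256, 64), n_dendrites=4,
                         synapse_density=0.0, seed=3)
    vol, truth = generate_scene(cfg)
    assert truth.synapses == []
    semantics = {info.semantic for info in vol.objects.values()}
    assert semantics == {"dendritic_shaft"}


def test_invalid_configs_are_rejected():
    with pytest.raises(ValueError):
        ScenarioConfig(as_fraction=1.5)
    with pytest.raises(ValueError):
        ScenarioConfig(voxel_size_nm=(5, 0, 20))
    with pytest.raises(ValueError):
        ScenarioConfig(target_mix={"AS": (1, 0, 0, 0), "SS": (0.5, 0, 0, 0)})


def test_every_truth_synapse_exists_in_volume(small_scene):
    vol, truth = small_scene
    present = set(vol.present_ids())
    for s in truth.synapses:
        assert s.synapse_id in present
        assert vol.semantic_of(s.synapse_id) == SYNAPSE


def test_truncation_flag_iff_touching_a_volume_face(small_scene):
    vol, truth = small_scene
    nz, ny, nx = vol.labels.shape
    # oracle: labels present on the six faces of the stack
    face_labels = set()
    for face in (vol.labels[0], vol.labels[-1], vol.labels[:, 0],
                 vol.labels[:, -1], vol.labels[:, :, 0],
                 vol.labels[:, :, -1]):
        face_labels.update(np.unique(face).tolist())
    face_labels.discard(0)
    for oid, flag in truth.object_truncated.items():
        assert flag == (oid in face_labels)


def test_as_fraction_recovered_within_binomial_interval():
    """Pooled scenes with ~1000 synapses: the AS count among the first
    1000 drawn lies in the central 99% binomial interval around 950."""
    cfg = ScenarioConfig(synapse_density=8.0, n_dendrites=16)
    types = []
    for seed in stack_seeds(424242, 8):
        _, truth = generate_scene(
            ScenarioConfig(**{**cfg.to_dict(), "seed": seed}))
        types += [s.syn_type for s in truth.synapses]
        if len(types) >= 1000:
            break
    n_as = sum(1 for t in types[:1000] if t == "AS")
    lo = sps.binom.ppf(0.005, 1000, 0.95)
    hi = sps.binom.ppf(0.995, 1000, 0.95)
    assert lo <= n_as <= hi


def test_marginal_mixes_recovered_at_n2000():
    """True (generator) type/target/shape draws fit the configured mixes
    (chi-square goodness of fit, p > 0.01 at ~2000 synapses)."""
    cfg = ScenarioConfig(synapse_density=8.0, n_dendrites=16)
    truths = []
    for seed in stack_seeds(99, 15):
        _, truth = generate_scene(
            ScenarioConfig(**{**cfg.to_dict(), "seed": seed}))
        truths += truth.synapses
    types = np.array([s.syn_type for s in truths])
    n = len(types)
    assert n >= 1900
    chi = sps.chisquare([np.sum(types == "AS"), np.sum(types == "SS")],
                        [n * 0.95, n * 0.05])
    assert chi.pvalue > 0.01
    from sasmorph.synthetic.config import TARGET_CLASSES
    tmix = {c: 0.95 * cfg.target_mix["AS"][i] + 0.05 * cfg.target_mix["SS"][i]
            for i, c in enumerate(TARGET_CLASSES)}
    targets = np.array([s.target_class for s in truths])
    obs = [np.sum(targets == c) for c in TARGET_CLASSES]
    chi = sps.chisquare(obs, [n * tmix[c] for c in TARGET_CLASSES])
    assert chi.pvalue > 0.01


def test_fixture_roundtrip(tmp_path, small_scene, small_config):
    vol, truth = small_scene
    out = write_fixture(vol, truth, tmp_path / "fx")
    vol2, truth2 = read_fixture(out)
    assert np.array_equal(vol.labels, vol2.labels)
    assert vol2.voxel_size_nm == tuple(small_config.voxel_size_nm)
    assert set(vol2.objects) == set(vol.objects)
    assert len(truth2.synapses) == len(truth.synapses)
    # sidecar object count equals ground-truth record count
    import json
    sidecar = json.loads((out / "sidecar.json").read_text())
    n_syn_sidecar = sum(1 for o in sidecar["objects"]
                        if o["semantic"] == "synapse")
    assert n_syn_sidecar == len(truth.synapses)


def test_pooled_analysis_joins_truth(small_config):
    df, truths = pooled_analysis(small_config, n_stacks=2, master_seed=5,
                                 with_metrics=False)
    assert {"true_type", "true_shape", "true_target"} <= set(df.columns)
    assert df.index.names == ["stack", "synapse_id"]
    assert len(truths) == 2
    assert not df["true_type"].isna().any()
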