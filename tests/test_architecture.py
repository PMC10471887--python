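"""Structural contracts of the dual-branch network.

The published layer table pins every intermediate shape and the exact
trainable-parameter total; the closed-form oracle here recounts parameters
per unit type independently of the builder's array-size bookkeeping.
"""

import numpy as np
import pytest

import dcfcnn.nn as nn
from dcfcnn.architecture import (
    MLF,
    MSF,
    ArchitectureConfig,
    DCFCNN,
    ResidualBlock,
    ablation_variants,
    build_dcfcnn,
    build_mlf,
    build_msf,
    build_residual_structure,
    build_rs_layer,
    count_trainable_params,
    shape_trace,
)
from dcfcnn.exceptions import ChannelMismatchError, ConfigError, FusionShapeError

PUBLISHED_TOTAL = 20_949_378

# (module, input HxWxC, output HxWxC) for a 448x448x3 input
PUBLISHED_TRACE = [
    ("MSF", (448, 448, 3), (224, 224, 64)),
    ("MLF_1", (224, 224, 64), (112, 112, 64)),
    ("MLF_2", (112, 112, 64), (56, 56, 128)),
    ("MLF_3", (56, 56, 128), (28, 28, 256)),
    ("RS_1", (448, 448, 3), (224, 224, 32)),
    ("RS_2", (224, 224, 32), (112, 112, 64)),
    ("RS_3", (112, 112, 64), (56, 56, 128)),
    ("RS_4", (56, 56, 128), (28, 28, 256)),
    ("RS_5", (28, 28, 256), (14, 14, 512)),
    ("Conv", (14, 14, 512), (14, 14, 1024)),
    ("AdaptiveAvgPool", (14, 14, 1024), (1, 1024)),
    ("Fully connect", (1, 1024), (1, 2)),
]


def closed_form_count(module) -> int:
    """Independent parameter tally: k*k*Cin*Cout (+Cout bias), 2C per BN,
    fin*fout+fout per linear — walks units by type, never reads array sizes."""
    total = 0
    if isinstance(module, nn.Conv2d):
        total += module.k * module.k * module.cin * module.cout
        if module.b is not None:
            total += module.cout
    elif isinstance(module, nn.BatchNorm2d):
        total += 2 * module.c
    elif isinstance(module, nn.Linear):
        total += module.fin * module.fout + module.fout
    for child in module._children:
        total += closed_form_count(child)
    return total


def test_default_model_reproduces_published_parameter_total():
    assert count_trainable_params(DCFCNN()) == PUBLISHED_TOTAL


def test_shape_trace_matches_published_table():
    assert shape_trace(DCFCNN(), (3, 448, 448)) == PUBLISHED_TRACE


@pytest.mark.parametrize("builder,args,expected", [
    (build_residual_structure, (32, 32, False), 2 * 9 * 32 * 32 + 2 * 2 * 32),
    (build_msf, (), (1 * 3 + 9 * 3 + 25 * 3 + 49 * 3) * 64 + 4 * 64 + 4 * 2 * 64),
    (build_mlf, (64, 64, True),
     64 * 64 + 3 * 64 * 64 + 4 * 64 + 4 * 2 * 64),
])
def test_unit_parameter_counts_match_hand_formulas(builder, args, expected):
    assert count_trainable_params(builder(*args)) == expected


@pytest.mark.parametrize("unit", [
    lambda: build_residual_structure(3, 32, True),
    lambda: build_residual_structure(64, 64, False),
    lambda: build_rs_layer(5, 256, 512),
    lambda: build_msf(),
    lambda: build_mlf(64, 128, False),
    lambda: DCFCNN(),
    lambda: DCFCNN(ArchitectureConfig(use_channel_branch=False)),
    lambda: DCFCNN(ArchitectureConfig(use_msf=False, rs1_first_stride=1)),
    lambda: DCFCNN(ArchitectureConfig(n_mlf=4)),
])
def test_builder_count_equals_closed_form_oracle(unit):
    m = unit()
    assert m.param_count() == closed_form_count(m)


def test_rs5_contains_three_structures_others_two():
    assert len(build_rs_layer(5, 256, 512).blocks) == 3
    for i, (ci, co) in enumerate([(3, 32), (32, 64), (64, 128), (128, 256)], 1):
        assert len(build_rs_layer(i, ci, co).blocks) == 2


def test_residual_stage_shapes():
    rs2 = build_rs_layer(2, 32, 64)
    assert rs2.out_shape((32, 224, 224)) == (64, 112, 112)
    rs1 = build_rs_layer(1, 3, 32, first_stride=1)
    assert rs1.out_shape((3, 448, 448)) == (32, 448, 448)


def test_downsampling_structure_halves_and_projects():
    blk = build_residual_structure(3, 32, True)
    assert blk.out_shape((3, 448, 448)) == (32, 224, 224)
    keep = build_residual_structure(32, 32, False)
    assert keep.out_shape((32, 224, 224)) == (32, 224, 224)


def test_shape_preserving_structure_rejects_unequal_channels():
    with pytest.raises(ChannelMismatchError):
        build_residual_structure(32, 64, False)


def test_msf_output_shapes():
    msf = build_msf()
    assert msf.out_shape((3, 448, 448)) == (64, 224, 224)
    assert msf.out_shape((3, 336, 336)) == (64, 168, 168)


def test_mlf_rejects_invalid_channel_pair():
    with pytest.raises(ConfigError):
        build_mlf(64, 256, True)


def test_mlf_shapes_match_published_rows():
    assert build_mlf(64, 64, True).out_shape((64, 224, 224)) == (64, 112, 112)
    assert build_mlf(64, 128, True).out_shape((64, 112, 112)) == (128, 56, 56)


def test_feature_reuse_changes_neither_shapes_nor_counts():
    on, off = build_mlf(64, 128, True), build_mlf(64, 128, False)
    assert on.out_shape((64, 112, 112)) == off.out_shape((64, 112, 112))
    assert on.param_count() == off.param_count()
    m_on = DCFCNN(ArchitectureConfig(feature_reuse=True))
    m_off = DCFCNN(ArchitectureConfig(feature_reuse=False))
    assert shape_trace(m_on) == shape_trace(m_off)
    assert m_on.param_count() == m_off.param_count()


@pytest.mark.parametrize("n_mlf", [1, 2, 3, 4])
def test_fusion_is_feasible_for_every_depth(n_mlf):
    """Channel-branch output must match RS_{n_mlf+1} output exactly."""
    model = DCFCNN(ArchitectureConfig(n_mlf=n_mlf))
    in_shape = (3, 448, 448)
    branch = model.channel_branch_shape(in_shape)
    s = in_shape
    for stage in model.rs_stages[:n_mlf + 1]:
        s = stage.out_shape(s)
    assert branch == s
    shape_trace(model, in_shape)  # raises on infeasible fusion
    if n_mlf == 4:
        assert branch[0] == 512  # deepest chain ends at 512 channels


def test_misaligned_fusion_raises_naming_both_shapes():
    # 1x1 stem without the stride-1 spatial adjustment cannot align
    model = DCFCNN(ArchitectureConfig(use_msf=False, rs1_first_stride=2))
    with pytest.raises(FusionShapeError) as exc:
        model.forward(np.zeros((1, 3, 64, 64), np.float32))
    assert exc.value.spatial_shape != exc.value.channel_shape


def test_removing_channel_branch_strictly_reduces_parameters():
    full = DCFCNN(ArchitectureConfig())
    spatial = DCFCNN(ArchitectureConfig(use_channel_branch=False))
    assert spatial.param_count() < full.param_count()


@pytest.mark.parametrize("name", list(ablation_variants()))
def test_forward_is_finite_for_every_ablation_variant(name):
    cfg = ablation_variants()[name]
    model = build_dcfcnn(cfg, seed=5)
    x = np.random.default_rng(0).normal(size=(2, 3, 64, 64)).astype(np.float32)
    out = model.forward(x, training=True)
    assert out.shape == (2, 2)
    assert np.isfinite(out).all()


def test_doubling_input_doubles_spatial_dimensions_only():
    m = DCFCNN()
    t1 = shape_trace(m, (3, 448, 448))
    t2 = shape_trace(m, (3, 896, 896))
    for (n1, i1, o1), (n2, i2, o2) in zip(t1, t2):
        assert n1 == n2
        if len(o1) == 3:  # spatial records
            assert o2[0] == 2 * o1[0] and o2[1] == 2 * o1[1] and o2[2] == o1[2]


def test_head_output_is_num_classes_for_every_variant():
    for cfg in ablation_variants().values():
        assert shape_trace(DCFCNN(cfg))[-1][2] == (1, 2)


def test_config_validation():
    with pytest.raises(ConfigError):
        ArchitectureConfig(n_mlf=5)
    with pytest.raises(ConfigError):
        ArchitectureConfig(rs1_first_stride=3)
    with pytest.raises(ConfigError):
        ArchitectureConfig(num_classes=1)


def test_fc_unit_parameter_count():
    assert nn.Linear(1024, 2).param_count() == 2050
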