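"""Forward-contract implementations of the detector's building blocks.

Three architectural units are provided as composable, inference-only NumPy
functions (no training, no autograd):

* the EfficientNetV2 backbone stage table (Conv3x3 stem, Fused-MBConv and
  MBConv stages with squeeze-excitation), tapped at strides 8/16/32 to
  produce a P3/P4/P5 feature pyramid;
* CSFF, a cross-scale feature fusion block: per-branch 1x1 channel
  adjustment, a stack of re-parameterizable RepBlocks, element-wise
  addition of the two adjacent-scale branches;
* SCSA, spatial-channel synergistic attention: a shared multi-semantic
  spatial gate (multi-kernel depthwise separable convolutions, Group
  Normalization, sigmoid) followed by progressive channel-wise single-head
  self-attention, combined with the input through a residual pathway.

Convolutions run as im2col + BLAS matmul in float32; weights live in plain
nested dicts of arrays so forwards are pure functions of (input, params).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as _expit

__all__ = [
    "StageSpec",
    "FeaturePyramid",
    "TABLE1_STAGES",
    "init_stage",
    "mb_stage_forward",
    "init_backbone",
    "build_backbone",
    "init_csff",
    "identity_csff_params",
    "csff_fuse",
    "init_scsa",
    "scsa_forward",
    "count_params",
    "csp_reference_param_count",
    "assemble_model",
    "save_params",
    "load_params",
]

_DT = np.float32


# ---------------------------------------------------------------------------
# functional primitives


def silu(x):
    return x * _expit(x)


def sigmoid(x):
    return _expit(x)


def conv2d(x, w, b=None, stride=1, padding=None):
    """2-D convolution on a (C, H, W) map; w is (Cout, Cin, kh, kw)."""
    cout, cin, kh, kw = w.shape
    c, h, wd = x.shape
    if c != cin:
        raise ValueError(f"channel mismatch: input {c}, weight expects {cin}")
    if padding is None:
        padding = kh // 2
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (C, Ho, Wo, kh, kw)
    _, ho, wo, _, _ = win.shape
    cols = win.transpose(1, 2, 0, 3, 4).reshape(ho * wo, cin * kh * kw)
    out = cols @ w.reshape(cout, -1).T
    if b is not None:
        out = out + b
    return np.ascontiguousarray(out.T.reshape(cout, ho, wo))


def depthwise_conv2d(x, w, stride=1, padding=None):
    """Depthwise convolution; w is (C, kh, kw)."""
    c, kh, kw = w.shape
    if x.shape[0] != c:
        raise ValueError(f"channel mismatch: input {x.shape[0]}, weight expects {c}")
    if padding is None:
        padding = kh // 2
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]
    return np.einsum("chwij,cij->chw", win, w, optimize=True).astype(x.dtype, copy=False)


def batchnorm(x, p, eps=1e-5):
    """Inference-mode normalization with stored statistics."""
    scale = (p["gamma"] / np.sqrt(p["var"] + eps)).astype(_DT)
    shift = (p["beta"] - p["mean"] * scale).astype(_DT)
    return x * scale[:, None, None] + shift[:, None, None]


def groupnorm(x, p, groups, eps=1e-5):
    c, h, w = x.shape
    g = x.reshape(groups, c // groups, h, w)
    mu = g.mean(axis=(1, 2, 3), keepdims=True)
    var = g.var(axis=(1, 2, 3), keepdims=True)
    g = (g - mu) / np.sqrt(var + eps)
    x = g.reshape(c, h, w)
    return x * p["gamma"][:, None, None] + p["beta"][:, None, None]


def _init_conv(rng, cout, cin, k):
    std = np.sqrt(2.0 / (cin * k * k))
    return rng.normal(0.0, std, size=(cout, cin, k, k)).astype(_DT)


def _init_bn(c):
    return {
        "gamma": np.ones(c, _DT),
        "beta": np.zeros(c, _DT),
        "mean": np.zeros(c, _DT),
        "var": np.ones(c, _DT),
    }


# ---------------------------------------------------------------------------
# stage table


@dataclass(frozen=True)
class StageSpec:
    operator: str  # conv3x3 | fused_mbconv | mbconv | head
    expansion: int
    kernel: int
    stride: int
    out_channels: int
    layers: int
    se_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.operator not in ("conv3x3", "fused_mbconv", "mbconv", "head"):
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2 (applied to the first layer)")
        if self.se_ratio and self.operator != "mbconv":
            raise ValueError("squeeze-excitation only belongs to MBConv stages")
        if self.expansion < 1 or self.out_channels < 1 or self.layers < 1:
            raise ValueError("expansion, out_channels and layers must be positive")


#: backbone stage table (stem + six MB stages; the classification head of the
#: original network is not part of the detection backbone).
TABLE1_STAGES: tuple[StageSpec, ...] = (
    StageSpec("conv3x3", 1, 3, 2, 24, 1),
    StageSpec("fused_mbconv", 1, 3, 1, 24, 2),
    StageSpec("fused_mbconv", 4, 3, 2, 48, 4),
    StageSpec("fused_mbconv", 4, 3, 2, 64, 4),
    StageSpec("mbconv", 4, 3, 2, 128, 6, 0.25),
    StageSpec("mbconv", 6, 3, 1, 160, 9, 0.25),
    StageSpec("mbconv", 6, 3, 2, 256, 15, 0.25),
)

#: pyramid taps: after stages 3/5/6 the cumulative strides are 8/16/32.
DEFAULT_TAPS = (3, 5, 6)


@dataclass
class FeaturePyramid:
    P3: np.ndarray
    P4: np.ndarray
    P5: np.ndarray


# ---------------------------------------------------------------------------
# MBConv / Fused-MBConv stages


def _init_layer(rng, spec: StageSpec, cin: int) -> dict:
    cout = spec.out_channels
    k = spec.kernel
    p: dict = {}
    if spec.operator == "conv3x3":
        p["conv"] = _init_conv(rng, cout, cin, k)
        p["bn"] = _init_bn(cout)
    elif spec.operator == "fused_mbconv":
        mid = cin * spec.expansion
        if spec.expansion == 1:
            p["fused"] = _init_conv(rng, cout, cin, k)
            p["fused_bn"] = _init_bn(cout)
        else:
            p["expand"] = _init_conv(rng, mid, cin, k)
            p["expand_bn"] = _init_bn(mid)
            p["project"] = _init_conv(rng, cout, mid, 1)
            p["project_bn"] = _init_bn(cout)
    elif spec.operator == "mbconv":
        mid = cin * spec.expansion
        p["expand"] = _init_conv(rng, mid, cin, 1)
        p["expand_bn"] = _init_bn(mid)
        p["dw"] = rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(mid, k, k)).astype(_DT)
        p["dw_bn"] = _init_bn(mid)
        if spec.se_ratio > 0:
            hidden = max(1, int(cin * spec.se_ratio))
            p["se_reduce"] = _init_conv(rng, hidden, mid, 1)
            p["se_reduce_b"] = np.zeros(hidden, _DT)
            p["se_expand"] = _init_conv(rng, mid, hidden, 1)
            p["se_expand_b"] = np.zeros(mid, _DT)
        p["project"] = _init_conv(rng, cout, mid, 1)
        p["project_bn"] = _init_bn(cout)
    else:
        raise ValueError(f"cannot initialize operator {spec.operator!r}")
    return p


def init_stage(spec: StageSpec, cin: int, rng) -> list[dict]:
    """Initialize one stage; the stride applies to the first layer only."""
    params = []
    for i in range(spec.layers):
        params.append(_init_layer(rng, spec, cin if i == 0 else spec.out_channels))
    return params


def _se_forward(x, p):
    s = x.mean(axis=(1, 2))[:, None, None]
    s = silu(conv2d(s, p["se_reduce"], p["se_reduce_b"], padding=0))
    s = sigmoid(conv2d(s, p["se_expand"], p["se_expand_b"], padding=0))
    return x * s


def _layer_forward(x, spec: StageSpec, p: dict, stride: int):
    cin = x.shape[0]
    if spec.operator == "conv3x3":
        return silu(batchnorm(conv2d(x, p["conv"], stride=stride), p["bn"]))
    residual = stride == 1 and cin == spec.out_channels
    if spec.operator == "fused_mbconv":
        if spec.expansion == 1:
            y = silu(batchnorm(conv2d(x, p["fused"], stride=stride), p["fused_bn"]))
        else:
            y = silu(batchnorm(conv2d(x, p["expand"], stride=stride), p["expand_bn"]))
            y = batchnorm(conv2d(y, p["project"], padding=0), p["project_bn"])
    else:  # mbconv
        y = silu(batchnorm(conv2d(x, p["expand"], padding=0), p["expand_bn"]))
        y = silu(batchnorm(depthwise_conv2d(y, p["dw"], stride=stride), p["dw_bn"]))
        if "se_reduce" in p:
            y = _se_forward(y, p)
        y = batchnorm(conv2d(y, p["project"], padding=0), p["project_bn"])
    return x + y if residual else y


def mb_stage_forward(x, spec: StageSpec, params: list[dict]):
    """Run one backbone stage (list of layers; stride on the first)."""
    for i, p in enumerate(params):
        x = _layer_forward(x, spec, p, spec.stride if i == 0 else 1)
    return x


# ---------------------------------------------------------------------------
# backbone


def init_backbone(stage_table=TABLE1_STAGES, in_channels: int = 3, seed: int = 0):
    rng = np.random.default_rng(seed)
    params = []
    cin = in_channels
    for spec in stage_table:
        params.append(init_stage(spec, cin, rng))
        cin = spec.out_channels
    return params


def build_backbone(x, params=None, stage_table=TABLE1_STAGES, taps=DEFAULT_TAPS,
                   seed: int = 0) -> FeaturePyramid:
    """Run the stage table on a (3, H, W) image and tap P3/P4/P5.

    The cumulative stride must reach 32 at the last tap (the standard
    detection pyramid); anything else is a configuration error.
    """
    stride = 1
    strides = []
    for spec in stage_table:
        stride *= spec.stride
        strides.append(stride)
    if strides[taps[-1]] != 32:
        raise ValueError(
            f"cumulative stride at last tap is {strides[taps[-1]]}, expected 32"
        )
    if params is None:
        params = init_backbone(stage_table, x.shape[0], seed)
    x = np.ascontiguousarray(x, dtype=_DT)
    feats = {}
    for i, (spec, p) in enumerate(zip(stage_table, params)):
        x = mb_stage_forward(x, spec, p)
        if i in taps:
            feats[i] = x
    p3, p4, p5 = (feats[i] for i in taps)
    return FeaturePyramid(P3=p3, P4=p4, P5=p5)


# ---------------------------------------------------------------------------
# CSFF


def _init_repblock(rng, c):
    return {
        "conv3": _init_conv(rng, c, c, 3),
        "bn3": _init_bn(c),
        "conv1": _init_conv(rng, c, c, 1),
        "bn1": _init_bn(c),
    }


def _repblock_forward(x, p, act="silu"):
    y = batchnorm(conv2d(x, p["conv3"]), p["bn3"]) \
        + batchnorm(conv2d(x, p["conv1"], padding=0), p["bn1"]) + x
    return silu(y) if act == "silu" else y


def init_csff(c_a: int, c_b: int, c_out: int, n_rep: int = 2, seed: int = 0,
              downsample_b: bool = False) -> dict:
    rng = np.random.default_rng(seed)
    p = {
        "adjust_a": _init_conv(rng, c_out, c_a, 1),
        "adjust_a_bn": _init_bn(c_out),
        "adjust_b": _init_conv(rng, c_out, c_b, 1),
        "adjust_b_bn": _init_bn(c_out),
        "rep_a": [_init_repblock(rng, c_out) for _ in range(n_rep)],
        "rep_b": [_init_repblock(rng, c_out) for _ in range(n_rep)],
        "act": "silu",
    }
    if downsample_b:
        p["down_b"] = _init_conv(rng, c_b, c_b, 3)
        p["down_b_bn"] = _init_bn(c_b)
    return p


def identity_csff_params(c: int, n_rep: int = 2) -> dict:
    """Identity-initialized block: 1x1 adjusts are identity matrices, the
    RepBlocks have zero convolutions and a linear (merged-deploy) activation,
    so each branch passes its input through unchanged."""
    eye = np.eye(c, dtype=_DT)[:, :, None, None]
    zero_rep = {
        "conv3": np.zeros((c, c, 3, 3), _DT), "bn3": _init_bn(c),
        "conv1": np.zeros((c, c, 1, 1), _DT), "bn1": _init_bn(c),
    }
    return {
        "adjust_a": eye.copy(), "adjust_a_bn": _init_bn(c),
        "adjust_b": eye.copy(), "adjust_b_bn": _init_bn(c),
        "rep_a": [dict(zero_rep) for _ in range(n_rep)],
        "rep_b": [dict(zero_rep) for _ in range(n_rep)],
        "act": "linear",
    }


def csff_fuse(feat_a, feat_b, params: dict):
    """Fuse two adjacent-scale features onto ``feat_a``'s grid.

    ``feat_b`` is resampled first (nearest 2x upsample if coarser, stride-2
    convolution if finer); each branch then runs its 1x1 channel adjust and
    RepBlock stack, and the branch results are added element-wise.
    """
    ha, wa = feat_a.shape[1:]
    hb, wb = feat_b.shape[1:]
    if (ha, wa) == (hb, wb):
        pass
    elif ha == 2 * hb and wa == 2 * wb:
        feat_b = np.repeat(np.repeat(feat_b, 2, axis=1), 2, axis=2)
    elif 2 * ha == hb and 2 * wa == wb:
        if "down_b" in params:
            feat_b = silu(batchnorm(conv2d(feat_b, params["down_b"], stride=2),
                                    params["down_b_bn"]))
        else:
            feat_b = feat_b[:, ::2, ::2]
    else:
        raise ValueError(
            f"scales {feat_a.shape[1:]} and {feat_b.shape[1:]} are not adjacent"
        )
    act = params.get("act", "silu")
    a = batchnorm(conv2d(feat_a.astype(_DT), params["adjust_a"], padding=0),
                  params["adjust_a_bn"])
    b = batchnorm(conv2d(feat_b.astype(_DT), params["adjust_b"], padding=0),
                  params["adjust_b_bn"])
    for p in params["rep_a"]:
        a = _repblock_forward(a, p, act)
    for p in params["rep_b"]:
        b = _repblock_forward(b, p, act)
    return a + b


# ---------------------------------------------------------------------------
# SCSA


def init_scsa(c: int, groups: int = 4, kernels=(3, 5, 7, 9), pool: int = 7,
              r: int = 4, seed: int = 0) -> dict:
    if c % groups:
        raise ValueError(f"channels {c} not divisible by {groups} groups")
    rng = np.random.default_rng(seed)
    cg = c // groups
    m = pool * pool
    dk = max(1, m // r)
    return {
        "dw": [rng.normal(0, np.sqrt(2.0 / (k * k)), (cg, k, k)).astype(_DT)
               for k in kernels],
        "pw": [_init_conv(rng, cg, cg, 1) for _ in kernels],
        "gn": {"gamma": np.ones(c, _DT), "beta": np.zeros(c, _DT)},
        "mix": _init_conv(rng, c, c, 1),
        "mix_b": np.zeros(c, _DT),
        "wq": rng.normal(0, np.sqrt(1.0 / m), (m, dk)).astype(_DT),
        "wk": rng.normal(0, np.sqrt(1.0 / m), (m, dk)).astype(_DT),
        "wo": rng.normal(0, np.sqrt(1.0 / c), (c, c)).astype(_DT),
        "wo_b": np.zeros(c, _DT),
        "pool": pool,
        "groups": groups,
    }


def _adaptive_avg_pool(x, out):
    c, h, w = x.shape
    ys = np.linspace(0, h, out + 1).round().astype(int)
    xs = np.linspace(0, w, out + 1).round().astype(int)
    p = np.empty((c, out, out), dtype=x.dtype)
    for i in range(out):
        r0 = min(ys[i], h - 1)
        r1 = max(r0 + 1, ys[i + 1])
        for j in range(out):
            c0 = min(xs[j], w - 1)
            c1 = max(c0 + 1, xs[j + 1])
            p[:, i, j] = x[:, r0:r1, c0:c1].mean(axis=(1, 2))
    return p


def _softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scsa_forward(x, params: dict, return_gates: bool = False):
    """Spatial-channel synergistic attention with a residual pathway.

    SMSA: channels split into equal groups, one depthwise-separable
    convolution per group with kernels 3/5/7/9, concatenation, Group
    Normalization, 1x1 mix, sigmoid -> spatial gate multiplied onto x.
    PCSA: the gated map is pooled to channel tokens, passed through
    compressed single-head self-attention and a sigmoid channel gate.
    Output = x + channel_gate * (spatial_gate * x).
    """
    x = np.ascontiguousarray(x, dtype=_DT)
    c = x.shape[0]
    groups = params["groups"]
    if c % groups:
        raise ValueError(f"channels {c} not divisible by {groups} groups")
    cg = c // groups
    # SMSA
    parts = []
    for g in range(groups):
        xg = x[g * cg:(g + 1) * cg]
        yg = depthwise_conv2d(xg, params["dw"][g])
        yg = conv2d(yg, params["pw"][g], padding=0)
        parts.append(yg)
    y = groupnorm(np.concatenate(parts, axis=0), params["gn"], groups)
    gate_pre = conv2d(y, params["mix"], params["mix_b"], padding=0)
    spatial_gate = sigmoid(gate_pre)
    s = spatial_gate * x
    # PCSA
    tokens = _adaptive_avg_pool(s, params["pool"]).reshape(c, -1)  # (C, m)
    q = tokens @ params["wq"]
    k = tokens @ params["wk"]
    attn = _softmax(q @ k.T / np.sqrt(q.shape[1]), axis=-1)  # (C, C)
    yv = attn @ tokens  # (C, m)
    chan_pre = params["wo"] @ yv.mean(axis=1) + params["wo_b"]
    channel_gate = sigmoid(chan_pre)
    out = x + channel_gate[:, None, None] * s
    if return_gates:
        return out, spatial_gate, channel_gate
    return out


# ---------------------------------------------------------------------------
# assembly, parameter counting, serialization


def count_params(tree) -> int:
    if isinstance(tree, np.ndarray):
        return tree.size
    if isinstance(tree, dict):
        return sum(count_params(v) for v in tree.values())
    if isinstance(tree, (list, tuple)):
        return sum(count_params(v) for v in tree)
    return 0


def assemble_model(stage_table=TABLE1_STAGES, neck_widths=(64, 160, 256),
                   n_rep: int = 2, seed: int = 0) -> dict:
    """Backbone + CSFF neck (P4->P3, P5->P4 fusions) + SCSA at each level."""
    rng_seed = seed
    taps = DEFAULT_TAPS
    tap_ch = [stage_table[i].out_channels for i in taps]
    params = {
        "backbone": init_backbone(stage_table, seed=rng_seed),
        "csff_p3": init_csff(tap_ch[0], tap_ch[1], neck_widths[0], n_rep, seed + 1),
        "csff_p4": init_csff(tap_ch[1], tap_ch[2], neck_widths[1], n_rep, seed + 2),
        "csff_p5": init_csff(tap_ch[2], tap_ch[1], neck_widths[2], n_rep, seed + 3,
                             downsample_b=True),
        "scsa": {f"P{i}": init_scsa(w, seed=seed + 4 + i)
                 for i, w in zip((3, 4, 5), neck_widths)},
    }
    return params


def forward_model(x, params: dict, stage_table=TABLE1_STAGES) -> FeaturePyramid:
    pyr = build_backbone(x, params["backbone"], stage_table)
    f3 = csff_fuse(pyr.P3, pyr.P4, params["csff_p3"])
    f4 = csff_fuse(pyr.P4, pyr.P5, params["csff_p4"])
    f5 = csff_fuse(pyr.P5, pyr.P4, params["csff_p5"])
    return FeaturePyramid(
        P3=scsa_forward(f3, params["scsa"]["P3"]),
        P4=scsa_forward(f4, params["scsa"]["P4"]),
        P5=scsa_forward(f5, params["scsa"]["P5"]),
    )


def csp_reference_param_count(stage_table=TABLE1_STAGES, in_channels: int = 3) -> int:
    """Parameter count of a conventional CSP/Darknet-style backbone with the
    classic channel-doubling schedule, matched in stage and block count.

    Computed from layer shapes only (nothing is allocated). Each stage is a
    3x3 downsampling convolution followed by `layers` residual bottlenecks
    (1x1 halving + 3x3 restoring), the standard cross-stage partial layout.
    """
    widths = []
    wch = 64
    for i in range(len(stage_table)):
        widths.append(min(wch, 1024))
        if i >= 1:
            wch *= 2
    total = 0
    cin = in_channels
    for spec, cout in zip(stage_table, widths):
        total += cin * cout * 9 + 2 * cout  # downsample conv + bn
        half = cout // 2
        for _ in range(spec.layers):
            total += cout * half + 2 * half       # 1x1 squeeze + bn
            total += half * cout * 9 + 2 * cout   # 3x3 restore + bn
        cin = cout
    return total


def save_params(path, params: dict) -> None:
    flat: dict[str, np.ndarray] = {}

    def walk(prefix, tree):
        if isinstance(tree, np.ndarray):
            flat[prefix] = tree
        elif isinstance(tree, dict):
            for k, v in tree.items():
                walk(f"{prefix}/{k}" if prefix else str(k), v)
        elif isinstance(tree, (list, tuple)):
            for i, v in enumerate(tree):
                walk(f"{prefix}/{i}", v)
        elif isinstance(tree, str):
            flat[prefix] = np.array(tree)

    walk("", params)
    np.savez(path, **flat)


def load_params(path) -> dict:
    with np.load(path, allow_pickle=False) as data:
        tree: dict = {}
        for key, arr in data.items():
            node = tree
            parts = key.split("/")
            for part in parts[:-1]:
                node = node.setdefault(part, {})
            node[parts[-1]] = arr if arr.ndim else (
                str(arr) if arr.dtype.kind in "US" else arr[()])

    def listify(node):
        if isinstance(node, dict):
            keys = list(node.keys())
            if keys and all(k.isdigit() for k in keys):
                return [listify(node[str(i)]) for i in range(len(keys))]
            return {k: listify(v) for k, v in node.items()}
        return node

    return listify(tree)
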