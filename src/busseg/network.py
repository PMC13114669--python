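"""Triple-branch segmentation network with adaptive feature fusion.

Encoder (CNN-anchored hierarchical parallel design): a residual CNN
backbone extracts features at four levels; at each level the CNN output
is fed *in parallel* to a visual state-space (VSS/Mamba) block and a
multi-head self-attention block, and the three branch maps are combined
by an Adaptive Feature Fusion Module (AFFM) — a softmax over per-sample
learned logits, so the fused map is a convex combination

    F_fused = sum_i w_i F_i,   w = softmax(a),   a = MLP(GAP(conv1x1(cat)))

The fused map of level l is the input of CNN stage l+1.  The decoder is
a U-Net++-style dense nested decoder (nodes X(i,j), i+j <= 3) producing
one logit map at input resolution.  Ablation variants swap branches,
fusion mechanism, decoder and loss.

Level resolutions: the stem downsamples x2 and stages 1-3 each x2, so
levels sit at 1/2, 1/4, 1/8, 1/16 of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import layers as nn
from .nn.tensor import Tensor, concat, no_grad, softmax, upsample_bilinear, where
from .ssm import SSMParams, ZOH_SMALL, selective_scan_op

BRANCHES = ("cnn", "mamba", "transformer")
VARIANT_NAMES = (
    "full_affm",
    "cnn_mamba",
    "cnn_transformer",
    "cnn_only",
    "concat_conv",
    "se_attention",
    "simple_average",
    "no_dbr_loss",
    "no_dense_decoder",
)


@dataclass
class ModelConfig:
    in_channels: int = 1
    image_size: int = 256
    level_channels: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_level: tuple[int, ...] = (3, 4, 6, 3)
    heads_per_level: tuple[int, ...] = (2, 4, 8, 16)
    mlp_ratio: float = 4.0
    dropout: float = 0.1
    affm_reduction: int = 4
    ssm: SSMParams = field(default_factory=SSMParams)
    decoder: str = "dense_nested"  # or "plain"
    fusion: str = "affm"  # "affm" | "concat_conv" | "se" | "average"
    branches: tuple[str, ...] = BRANCHES
    seed: int = 0

    def __post_init__(self):
        ch = self.level_channels
        if any(a >= b for a, b in zip(ch, ch[1:])):
            raise ValueError("level_channels must be strictly increasing")
        for c, h in zip(ch, self.heads_per_level):
            if c % h != 0:
                raise ValueError(f"heads {h} must divide channels {c}")
        if "cnn" not in self.branches:
            raise ValueError("the cnn branch is the anchor and cannot be removed")
        for b in self.branches:
            if b not in BRANCHES:
                raise ValueError(f"unknown branch {b!r}")
        if self.decoder not in ("dense_nested", "plain"):
            raise ValueError(f"unknown decoder {self.decoder!r}")
        if self.fusion not in ("affm", "concat_conv", "se", "average"):
            raise ValueError(f"unknown fusion {self.fusion!r}")


MINIATURE = ModelConfig(
    image_size=64,
    level_channels=(8, 16, 32, 64),
    blocks_per_level=(1, 1, 1, 1),
    heads_per_level=(1, 2, 2, 4),
    ssm=SSMParams(d_state=8),
)


# --------------------------------------------------------------------- blocks
class ResidualBlock(nn.Module):
    """Two 3x3 conv + BN with identity or 1x1-projection shortcut."""

    def __init__(self, c_in, c_out, stride=1):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.short = nn.Sequential(nn.Conv2d(c_in, c_out, 1, stride=stride, bias=False), nn.BatchNorm2d(c_out))
        else:
            self.short = None

    def forward(self, x):
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        s = self.short(x) if self.short is not None else x
        return (y + s).relu()


class CNNStem(nn.Module):
    def __init__(self, c_in, c_out):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, 7, stride=2, padding=3, bias=False)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class CNNStage(nn.Module):
    """One encoder stage: n residual blocks; stages >0 downsample x2 on entry."""

    def __init__(self, c_in, c_out, n_blocks, downsample):
        super().__init__()
        blocks = [ResidualBlock(c_in, c_out, stride=2 if downsample else 1)]
        blocks += [ResidualBlock(c_out, c_out) for _ in range(n_blocks - 1)]
        self.blocks = nn.ModuleList(blocks)

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        return x


class MLP(nn.Module):
    def __init__(self, dim, ratio, dropout_p):
        super().__init__()
        hidden = int(dim * ratio)
        self.fc1 = nn.Linear(dim, hidden)
        self.fc2 = nn.Linear(hidden, dim)
        self.drop = nn.Dropout(dropout_p)

    def forward(self, x):
        return self.fc2(self.drop(self.fc1(x).silu()))


def _reorder(t: Tensor, direction: int, H: int, W: int, inverse: bool = False) -> Tensor:
    """Reorder a (B, L, ...) token tensor for one of the four scan
    directions: row-major forward/backward, column-major forward/backward.
    Flips and the row/column transpose are involutions, so the inverse is
    the same pair of ops applied in reverse order."""
    if direction == 0:
        return t
    trail = t.shape[2:]

    def transpose_grid(u, h, w):
        u = u.reshape(u.shape[0], h, w, *trail)
        axes = (0, 2, 1) + tuple(range(3, u.ndim))
        return u.transpose(axes).reshape(u.shape[0], h * w, *trail)

    fwd = {
        1: [lambda u: u.flip(1)],
        2: [lambda u: transpose_grid(u, H, W)],
        3: [lambda u: transpose_grid(u, H, W), lambda u: u.flip(1)],
    }[direction]
    inv = {
        1: [lambda u: u.flip(1)],
        2: [lambda u: transpose_grid(u, W, H)],
        3: [lambda u: u.flip(1), lambda u: transpose_grid(u, W, H)],
    }[direction]
    for op in inv if inverse else fwd:
        t = op(t)
    return t


class SS2D(nn.Module):
    """2-D selective scan: expand -> depthwise conv -> 4-direction S6 -> gate."""

    def __init__(self, dim, params: SSMParams):
        super().__init__()
        self.dim = dim
        self.params = params
        self.inner = params.expand * dim
        self.dt_rank = params.resolve_dt_rank(self.inner)
        N = params.d_state
        self.in_proj = nn.Linear(dim, 2 * self.inner)
        self.dwconv = nn.DepthwiseConv2d(self.inner, params.conv_kernel, padding=params.conv_kernel // 2)
        self.x_proj = nn.Linear(self.inner, self.dt_rank + 2 * N, bias=False)
        self.dt_proj = nn.Linear(self.dt_rank, self.inner)
        # dt bias: softplus(bias) spread over [1e-3, 1e-1]
        dt = np.exp(nn.get_rng().uniform(np.log(1e-3), np.log(1e-1), self.inner))
        self.dt_proj.b.data = np.log(np.expm1(dt)).astype(np.float32)
        # A = -(1..N) per inner channel (stored as log for positivity)
        self.A_log = Tensor(np.log(np.tile(np.arange(1, N + 1, dtype=np.float32), (self.inner, 1))), requires_grad=True)
        self.out_proj = nn.Linear(self.inner, dim)

    def forward(self, x: Tensor, H: int, W: int) -> Tensor:
        # x: (B, L, C) tokens on an HxW grid
        B, L, _ = x.shape
        N = self.params.d_state
        xz = self.in_proj(x)
        u = xz[:, :, : self.inner]
        z = xz[:, :, self.inner :]
        # depthwise 2-D conv over the token grid
        u2 = u.transpose(0, 2, 1).reshape(B, self.inner, H, W)
        u2 = self.dwconv(u2)
        u = u2.reshape(B, self.inner, L).transpose(0, 2, 1).silu()

        proj = self.x_proj(u)
        delta = self.dt_proj(proj[:, :, : self.dt_rank]).softplus()  # (B,L,D)
        Bmat = proj[:, :, self.dt_rank : self.dt_rank + N]  # (B,L,N)
        Cmat = proj[:, :, self.dt_rank + N :]  # (B,L,N)

        A = -self.A_log.exp()  # (D,N), negative diagonal
        dA = delta.reshape(B, L, self.inner, 1) * A.reshape(1, 1, self.inner, N)
        A_bar = dA.exp()
        small = np.abs(dA.data) < ZOH_SMALL
        safe_A = where(small, Tensor(np.ones_like(dA.data)), A.reshape(1, 1, self.inner, N) + Tensor(np.zeros_like(dA.data)))
        dB = delta.reshape(B, L, self.inner, 1) * Bmat.reshape(B, L, 1, N)
        B_bar = where(small, dB * (dA * 0.5 + 1.0), (A_bar - 1.0) / safe_A * Bmat.reshape(B, L, 1, N))
        Bx = B_bar * u.reshape(B, L, self.inner, 1)

        # four scan directions stacked into the batch axis, one recurrence
        Ab4 = concat([_reorder(A_bar, d, H, W) for d in range(4)], axis=0)
        Bx4 = concat([_reorder(Bx, d, H, W) for d in range(4)], axis=0)
        C4 = concat([_reorder(Cmat, d, H, W) for d in range(4)], axis=0)
        y4 = selective_scan_op(Ab4, Bx4, C4)
        ys = [_reorder(y4[d * B : (d + 1) * B], d, H, W, inverse=True) for d in range(4)]
        y = (ys[0] + ys[1] + ys[2] + ys[3]) * 0.25
        return self.out_proj(y * z.silu())


class VSSBlock(nn.Module):
    """Visual state-space block: pre-norm SS2D + feed-forward, residual."""

    def __init__(self, dim, params: SSMParams, mlp_ratio=4.0, dropout_p=0.1):
        super().__init__()
        self.ln1 = nn.LayerNorm(dim)
        self.ss2d = SS2D(dim, params)
        self.ln2 = nn.LayerNorm(dim)
        self.mlp = MLP(dim, mlp_ratio, dropout_p)
        self.drop = nn.Dropout(dropout_p)

    def forward(self, fmap: Tensor) -> Tensor:
        B, C, H, W = fmap.shape
        x = fmap.reshape(B, C, H * W).transpose(0, 2, 1)  # tokens
        x = x + self.drop(self.ss2d(self.ln1(x), H, W))
        x = x + self.mlp(self.ln2(x))
        return x.transpose(0, 2, 1).reshape(B, C, H, W)


class TransformerBlock(nn.Module):
    """Pre-norm multi-head self-attention + MLP over flattened pixels.

    Positional information comes from learned, factorized row/column
    embeddings (summed), sized for ``grid`` and bilinearly resampled if
    the block is applied to a different grid.
    """

    def __init__(self, dim, heads, grid: tuple[int, int], mlp_ratio=4.0, dropout_p=0.1):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"heads {heads} must divide dim {dim}")
        self.heads = heads
        self.dim = dim
        self.grid = grid
        self.ln1 = nn.LayerNorm(dim)
        self.qkv = nn.Linear(dim, 3 * dim)
        self.proj = nn.Linear(dim, dim)
        self.ln2 = nn.LayerNorm(dim)
        self.mlp = MLP(dim, mlp_ratio, dropout_p)
        self.drop = nn.Dropout(dropout_p)
        s = 0.02
        self.pos_rows = Tensor((nn.get_rng().standard_normal((grid[0], dim)) * s).astype(np.float32), requires_grad=True)
        self.pos_cols = Tensor((nn.get_rng().standard_normal((grid[1], dim)) * s).astype(np.float32), requires_grad=True)
        self.last_attention: np.ndarray | None = None

    def _pos(self, H, W):
        pr, pc = self.pos_rows, self.pos_cols
        if (H, W) != self.grid:
            pr = upsample_bilinear(pr.transpose(1, 0).reshape(1, self.dim, self.grid[0], 1), H, 1).reshape(self.dim, H).transpose(1, 0)
            pc = upsample_bilinear(pc.transpose(1, 0).reshape(1, self.dim, self.grid[1], 1), W, 1).reshape(self.dim, W).transpose(1, 0)
        pos = pr.reshape(H, 1, self.dim) + pc.reshape(1, W, self.dim)
        return pos.reshape(1, H * W, self.dim)

    def forward(self, fmap: Tensor) -> Tensor:
        B, C, H, W = fmap.shape
        L = H * W
        x = fmap.reshape(B, C, L).transpose(0, 2, 1) + self._pos(H, W)
        h = self.heads
        dh = C // h
        qkv = self.qkv(self.ln1(x)).reshape(B, L, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B,h,L,dh)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data.mean(axis=1)  # head-averaged (B,L,L)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, C)
        x = x + self.drop(self.proj(out))
        x = x + self.mlp(self.ln2(x))
        return x.transpose(0, 2, 1).reshape(B, C, H, W)


# --------------------------------------------------------------------- fusion
class AFFM(nn.Module):
    """Adaptive feature fusion: per-sample softmax weights over branches."""

    def __init__(self, channels, n_branches, reduction=4):
        super().__init__()
        self.n_branches = n_branches
        hidden = max(channels // reduction, 1)
        self.reduce = nn.Conv2d(n_branches * channels, channels, 1)
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, n_branches)

    def logits(self, maps):
        x = self.reduce(concat(maps, axis=1))
        g = x.mean(axis=(2, 3))  # GAP -> (B, C)
        return self.fc2(self.fc1(g).relu())  # (B, n_branches)

    def forward(self, maps, deactivate=(), force_weights=None):
        shapes = {m.shape for m in maps}
        if len(shapes) != 1:
            raise ValueError("branch maps must share a shape")
        if force_weights is not None:
            w_data = np.broadcast_to(np.asarray(force_weights, dtype=maps[0].dtype), (maps[0].shape[0], self.n_branches))
            w = Tensor(np.array(w_data))
        else:
            a = self.logits(maps)
            if deactivate:
                mask = np.zeros(self.n_branches, dtype=bool)
                mask[list(deactivate)] = True
                a = where(np.broadcast_to(mask, a.shape), Tensor(np.full(a.shape, -1e9, dtype=a.dtype)), a)
            w = softmax(a, axis=-1)
        B = maps[0].shape[0]
        fused = None
        for i, m in enumerate(maps):
            term = w[:, i].reshape(B, 1, 1, 1) * m
            fused = term if fused is None else fused + term
        return fused, w


class ConcatConvFusion(nn.Module):
    def __init__(self, channels, n_branches):
        super().__init__()
        self.conv = nn.Conv2d(n_branches * channels, channels, 1)

    def forward(self, maps, **_):
        return self.conv(concat(maps, axis=1)), None


class SEFusion(nn.Module):
    """Concat -> 1x1 conv -> squeeze-excitation channel gating."""

    def __init__(self, channels, n_branches, reduction=4):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.conv = nn.Conv2d(n_branches * channels, channels, 1)
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)

    def forward(self, maps, **_):
        x = self.conv(concat(maps, axis=1))
        B, C = x.shape[:2]
        gate = self.fc2(self.fc1(x.mean(axis=(2, 3))).relu()).sigmoid()
        return x * gate.reshape(B, C, 1, 1), None


class AverageFusion(nn.Module):
    def __init__(self, *_args, **_kw):
        super().__init__()

    def forward(self, maps, **_):
        out = maps[0]
        for m in maps[1:]:
            out = out + m
        return out * (1.0 / len(maps)), None


def fuse_alternatives(f_list, mode: str):
    """Parameter-free/functional fusion used by tests and ablations."""
    if mode == "average":
        return AverageFusion()(f_list)[0]
    channels = f_list[0].shape[1]
    if mode == "concat_conv":
        return ConcatConvFusion(channels, len(f_list))(f_list)[0]
    if mode == "se":
        return SEFusion(channels, len(f_list))(f_list)[0]
    raise ValueError(f"unknown fusion mode {mode!r}")


# -------------------------------------------------------------------- decoder
class DecoderNode(nn.Module):
    def __init__(self, c_in, c_out):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, 3, padding=1, bias=False)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class DenseDecoder(nn.Module):
    """U-Net++-style nested decoder over 4 encoder levels.

    Node X(i,j) (i+j <= 3, j >= 1) receives all X(i, 0..j-1) plus the
    bilinearly upsampled X(i+1, j-1); row widths equal the encoder width
    of their level.  The head maps X(0,3) to a 1-channel logit map and
    upsamples it to the input resolution.
    """

    rows = 4

    def __init__(self, channels):
        super().__init__()
        self.channels = channels
        self.nodes = nn.ModuleList()
        self.node_index = {}
        for j in range(1, self.rows):
            for i in range(self.rows - j):
                c_in = j * channels[i] + channels[i + 1]
                self.node_index[(i, j)] = len(self.nodes)
                self.nodes.append(DecoderNode(c_in, channels[i]))
        self.head = nn.Conv2d(channels[0], 1, 1)
        # logit-bias prior: lesions cover a minority of pixels, so start
        # the head predicting background (sigmoid(-2) ~ 0.12)
        self.head.b.data[:] = -2.0

    def node_names(self):
        return [f"X({i},{j})" for (i, j) in self.node_index]

    def forward(self, feats, out_size, record=None):
        X = {(i, 0): f for i, f in enumerate(feats)}
        for j in range(1, self.rows):
            for i in range(self.rows - j):
                below = X[(i + 1, j - 1)]
                up = upsample_bilinear(below, X[(i, 0)].shape[2], X[(i, 0)].shape[3])
                inp = concat([X[(i, k)] for k in range(j)] + [up], axis=1)
                X[(i, j)] = self.nodes[self.node_index[(i, j)]](inp)
                if record is not None:
                    record[f"X({i},{j})"] = X[(i, j)]
        logits = self.head(X[(0, self.rows - 1)])
        return upsample_bilinear(logits, out_size, out_size)


class PlainDecoder(nn.Module):
    """Standard U-Net decoder: only the X(i,1) chain."""

    def __init__(self, channels):
        super().__init__()
        self.channels = channels
        self.nodes = nn.ModuleList(
            [DecoderNode(channels[i] + channels[i + 1], channels[i]) for i in range(3)]
        )
        self.head = nn.Conv2d(channels[0], 1, 1)
        self.head.b.data[:] = -2.0

    def node_names(self):
        return [f"X({i},1)" for i in range(3)]

    def forward(self, feats, out_size, record=None):
        x = feats[3]
        for i in (2, 1, 0):
            up = upsample_bilinear(x, feats[i].shape[2], feats[i].shape[3])
            x = self.nodes[i](concat([feats[i], up], axis=1))
            if record is not None:
                record[f"X({i},1)"] = x
        return upsample_bilinear(self.head(x), out_size, out_size)


# ---------------------------------------------------------------------- model
class SegModel(nn.Module):
    """The full segmentation network (branches per config)."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        ch = config.level_channels
        with_mamba = "mamba" in config.branches
        with_trans = "transformer" in config.branches
        self.branch_names = ["cnn"] + (["mamba"] if with_mamba else []) + (["transformer"] if with_trans else [])
        n_br = len(self.branch_names)

        self.stem = CNNStem(config.in_channels, ch[0])
        self.stages = nn.ModuleList(
            [
                CNNStage(ch[l - 1] if l else ch[0], ch[l], config.blocks_per_level[l], downsample=l > 0)
                for l in range(4)
            ]
        )
        grid0 = config.image_size // 2
        self.vss = nn.ModuleList(
            [VSSBlock(ch[l], config.ssm, config.mlp_ratio, config.dropout) for l in range(4)]
        ) if with_mamba else None
        self.transformer = nn.ModuleList(
            [
                TransformerBlock(
                    ch[l], config.heads_per_level[l], (grid0 >> l, grid0 >> l), config.mlp_ratio, config.dropout
                )
                for l in range(4)
            ]
        ) if with_trans else None

        if n_br == 1:
            self.fusion = None
        elif config.fusion == "affm":
            self.fusion = nn.ModuleList([AFFM(ch[l], n_br, config.affm_reduction) for l in range(4)])
        elif config.fusion == "concat_conv":
            self.fusion = nn.ModuleList([ConcatConvFusion(ch[l], n_br) for l in range(4)])
        elif config.fusion == "se":
            self.fusion = nn.ModuleList([SEFusion(ch[l], n_br, config.affm_reduction) for l in range(4)])
        else:
            self.fusion = nn.ModuleList([AverageFusion() for _ in range(4)])

        self.decoder = DenseDecoder(ch) if config.decoder == "dense_nested" else PlainDecoder(ch)
        self.activations: dict[str, Tensor] = {}

    # ------------------------------------------------------------------
    def forward(self, x, record: bool = False, deactivate=(), force_fusion_weights=None):
        """Returns ``(logits, fusion_weights)``.

        ``fusion_weights`` is a list of 4 per-sample weight arrays (one
        per level; None for non-AFFM fusion).  ``deactivate`` names
        branches whose AFFM weight is pinned to zero (renormalized);
        ``force_fusion_weights`` overrides the weights entirely.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[2] != x.shape[3]:
            raise ValueError("input must be (B, C, H, W) with H == W")
        if not np.isfinite(x.data).all():
            raise ValueError("input contains non-finite values")
        self.activations = {}
        deact_idx = [self.branch_names.index(b) for b in deactivate]
        if "cnn" in deactivate:
            raise ValueError("the cnn anchor branch cannot be deactivated")

        feats, weights = [], []
        cur = self.stem(x)
        for l in range(4):
            f_cnn = self.stages[l](cur)
            maps = [f_cnn]
            if self.vss is not None:
                maps.append(self.vss[l](f_cnn))
            if self.transformer is not None:
                maps.append(self.transformer[l](f_cnn))
            if record:
                for name, m in zip(self.branch_names, maps):
                    m.retain_grad()
                    self.activations[f"{name}_l{l}"] = m
            if self.fusion is None:
                fused, w = f_cnn, None
            elif isinstance(self.fusion[l], AFFM):
                fused, w = self.fusion[l](maps, deactivate=deact_idx, force_weights=force_fusion_weights)
                w = w.data.copy()
            else:
                fused, w = self.fusion[l](maps)
            if record:
                fused.retain_grad()
                self.activations[f"fused_l{l}"] = fused
            feats.append(fused)
            weights.append(w)
            cur = fused
        rec = self.activations if record else None
        logits = self.decoder(feats, x.shape[2], record=rec)
        if record:
            for t in self.activations.values():
                t.retain_grad()
        return logits, weights

    def predict_proba(self, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Sigmoid probability maps for (N,H,W) images, in eval mode."""
        was_training = self.training
        self.eval()
        out = []
        images = np.asarray(images, dtype=np.float32)
        for i in range(0, len(images), batch_size):
            batch = images[i : i + batch_size][:, None]
            with no_grad():
                logits, _ = self.forward(Tensor(batch))
            out.append(1.0 / (1.0 + np.exp(-logits.data[:, 0])))
        self.train(was_training)
        return np.concatenate(out, axis=0)


def build_model(config: ModelConfig) -> SegModel:
    """Build a model with parameters initialized from ``config.seed``."""
    with nn.rng_seed(config.seed):
        return SegModel(config)


# ------------------------------------------------------------------- variants
@dataclass
class VariantSpec:
    """One row of the nine-variant ablation: config + loss override."""

    name: str

    def __post_init__(self):
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant {self.name!r}; valid: {VARIANT_NAMES}")

    def model_config(self, base: ModelConfig) -> ModelConfig:
        n = self.name
        if n in ("full_affm", "no_dbr_loss"):
            return replace(base)
        if n == "cnn_mamba":
            return replace(base, branches=("cnn", "mamba"))
        if n == "cnn_transformer":
            return replace(base, branches=("cnn", "transformer"))
        if n == "cnn_only":
            return replace(base, branches=("cnn",))
        if n == "concat_conv":
            return replace(base, fusion="concat_conv")
        if n == "se_attention":
            return replace(base, fusion="se")
        if n == "simple_average":
            return replace(base, fusion="average")
        if n == "no_dense_decoder":
            return replace(base, decoder="plain")
        raise AssertionError(n)

    def loss_config(self, base=None):
        from .losses import LossConfig, PLAIN_BCE_DICE

        if self.name == "no_dbr_loss":
            return PLAIN_BCE_DICE
        return base if base is not None else LossConfig()


def build_variant(name: str, base: ModelConfig):
    """Returns ``(model, loss_config)`` for one ablation variant."""
    spec = VariantSpec(name)
    return build_model(spec.model_config(base)), spec.loss_config()
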