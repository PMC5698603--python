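"""The convolutional classifier family: patch codes, pooling strides, training.

Each model is one convolution stage + one max-pooling stage + one hidden
layer + a 2-class softmax, trained with mini-batch stochastic gradient
descent (learning rate 0.008, batch size 100). The family is indexed by a
two-digit *patch code*: the first digit selects the convolution patch, the
second the pool patch, from the fixed tables

    conv: 0=[3x3] 1=[2x2] 2=[3x2] 3=[2x3] 4=[2x4] 5=[1x4]
    pool: 0=[2x2] 1=[3x3] 2=[1x2] 3=[1x3] 4=[2x3]

so code "24" means conv [3x2] with pool [2x3] — 30 models in all. The pool
stride is either "default" (equal to the pool patch, non-overlapping) or one
of the fixed strides [1x1], [1x2], [1x3], [2x2], [2x3]; a stride smaller
than the patch makes pooling windows overlap.

For the grid-shaped input (10, 11, 28) the convolution is spatial: one
shared 2D kernel slides (stride 1, valid) over each of the 28 time slices,
producing 28 feature maps, one per time sample. Pooling windows whose origin
lies inside a map are kept and truncated at the boundary, so the whole map
is spanned for every stride.

Everything is plain numpy with explicit backpropagation; the network is
small enough (a few hundred weights) that this trains in seconds on a CPU.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

CONV_PATCHES: tuple[tuple[int, int], ...] = (
    (3, 3), (2, 2), (3, 2), (2, 3), (2, 4), (1, 4),
)
POOL_PATCHES: tuple[tuple[int, int], ...] = (
    (2, 2), (3, 3), (1, 2), (1, 3), (2, 3),
)
POOL_STRIDES: tuple[str, ...] = (
    "default", "1x1", "1x2", "1x3", "2x2", "2x3",
)
PATCH_CODES: tuple[str, ...] = tuple(
    f"{c}{p}" for c in range(len(CONV_PATCHES)) for p in range(len(POOL_PATCHES))
)  # 30 codes


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchConfig:
    """Resolved patch code: convolution patch, pool patch, pool stride."""

    code: str
    conv_patch: tuple[int, int]
    pool_patch: tuple[int, int]
    pool_stride: tuple[int, int]
    stride_name: str = "default"


def decode_patch_code(code: str, stride: str = "default") -> PatchConfig:
    """Resolve a two-digit patch code (and stride name) to concrete shapes.

    The first digit indexes the convolution patch (0-5), the second the pool
    patch (0-4). ``stride`` is "default" (stride = pool patch) or "HxW".
    """
    if len(code) != 2 or not code.isdigit():
        raise ValueError(f"patch code must be two digits, got {code!r}")
    ci, pi = int(code[0]), int(code[1])
    if ci >= len(CONV_PATCHES):
        raise ValueError(f"convolution patch digit {ci} out of range 0-5")
    if pi >= len(POOL_PATCHES):
        raise ValueError(f"pool patch digit {pi} out of range 0-4")
    pool_patch = POOL_PATCHES[pi]
    if stride == "default":
        pool_stride = pool_patch
    else:
        try:
            sx, sy = stride.split("x")
            pool_stride = (int(sx), int(sy))
        except ValueError as exc:
            raise ValueError(f"stride must be 'default' or 'HxW', got {stride!r}") from exc
        if pool_stride[0] < 1 or pool_stride[1] < 1:
            raise ValueError("stride components must be >= 1")
    return PatchConfig(
        code=code,
        conv_patch=CONV_PATCHES[ci],
        pool_patch=pool_patch,
        pool_stride=pool_stride,
        stride_name=stride,
    )


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters; defaults follow the study (lr 0.008, batch 100)."""

    learning_rate: float = 0.008
    batch_size: int = 100
    n_epochs: int = 100
    hidden_units: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """Input kind + patches; layer shapes follow from these."""

    patches: PatchConfig
    input_kind: str = "3d"  # "3d" (10, 11, 28) or "2d" (64, 28)
    per_slice_kernels: bool = False  # one kernel per time slice instead of shared

    def __post_init__(self) -> None:
        if self.input_kind not in ("3d", "2d"):
            raise ValueError("input_kind must be '3d' or '2d'")
        h, w = self.input_shape[:2]
        kh, kw = self.patches.conv_patch
        if kh > h or kw > w:
            raise ValueError(
                f"conv patch {self.patches.conv_patch} exceeds input plane ({h}, {w})"
            )
        mh, mw = conv_output_shape((h, w), self.patches.conv_patch)
        ph, pw = self.patches.pool_patch
        if ph > mh or pw > mw:
            raise ValueError(
                f"pool patch {self.patches.pool_patch} exceeds feature map ({mh}, {mw})"
            )

    @property
    def input_shape(self) -> tuple[int, int, int]:
        # 2D inputs are handled as a single 64 x 28 "slice"
        return (10, 11, 28) if self.input_kind == "3d" else (64, 28, 1)

    @property
    def n_feature_maps(self) -> int:
        return self.input_shape[2]


# ---------------------------------------------------------------------------
# shape arithmetic (shared with the brute-force test oracles)
# ---------------------------------------------------------------------------

def conv_output_shape(plane: tuple[int, int], patch: tuple[int, int]) -> tuple[int, int]:
    """Valid convolution, stride 1: (H - h + 1, W - w + 1)."""
    out = (plane[0] - patch[0] + 1, plane[1] - patch[1] + 1)
    if out[0] < 1 or out[1] < 1:
        raise ValueError(f"patch {patch} larger than plane {plane}")
    return out


def pool_output_shape(plane: tuple[int, int], stride: tuple[int, int]) -> tuple[int, int]:
    """Window origins on a stride lattice; any origin inside the map counts.

    Windows are truncated at the boundary, so the output size depends only on
    the stride: floor((dim - 1) / stride) + 1 per axis.
    """
    if stride[0] < 1 or stride[1] < 1:
        raise ValueError("stride components must be >= 1")
    return ((plane[0] - 1) // stride[0] + 1, (plane[1] - 1) // stride[1] + 1)


def enumerate_grid(
    n_subjects: int = 9,
    trial_lengths: tuple[float, ...] = (500.0, 400.0, 300.0),
    strides: tuple[str, ...] = POOL_STRIDES,
    codes: tuple[str, ...] = PATCH_CODES,
) -> list[dict]:
    """Deterministic Cartesian product of the experiment grid.

    The full study grid — 30 codes x 6 strides x 9 subjects x 3 trial
    lengths — has 4860 cells, one trained network each.
    """
    return [
        {
            "subject": subj,
            "trial_length_ms": tl,
            "patch_code": code,
            "pool_stride": stride,
        }
        for subj, tl, code, stride in itertools.product(
            range(1, n_subjects + 1), trial_lengths, codes, strides
        )
    ]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def conv_per_slice(
    x: np.ndarray, kernel: np.ndarray, bias: float | np.ndarray = 0.0
) -> np.ndarray:
    """Slide a 2D kernel over every time slice of x (valid, stride 1).

    x: (..., H, W, T); kernel (h, w) shared across slices, or (T, h, w) for
    per-slice kernels. Returns (..., H-h+1, W-w+1, T) — with the grid input,
    28 feature maps, one per time sample. Cross-correlation orientation, as
    usual for CNNs. No nonlinearity here.
    """
    x = np.asarray(x, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    h, w = kernel.shape[-2:]
    if h > x.shape[-3] or w > x.shape[-2]:
        raise ValueError(
            f"kernel {(h, w)} larger than input plane {x.shape[-3:-1]}"
        )
    win = sliding_window_view(x, (h, w), axis=(-3, -2))  # (..., H', W', T, h, w)
    if kernel.ndim == 2:
        return np.einsum("...tij,ij->...t", win, kernel) + bias
    return np.einsum("...tij,tij->...t", win, kernel) + bias


def _pad_for_pool(
    plane: tuple[int, int], patch: tuple[int, int], stride: tuple[int, int]
) -> tuple[int, int]:
    """Padded plane size so every (possibly truncated) window is full-size."""
    nr, nc = pool_output_shape(plane, stride)
    return ((nr - 1) * stride[0] + patch[0], (nc - 1) * stride[1] + patch[1])


def max_pool(
    maps: np.ndarray,
    patch: tuple[int, int],
    stride: tuple[int, int] | None = None,
    return_argmax: bool = False,
):
    """Max-pool the two leading spatial axes of (..., H, W, T) maps.

    Window origins sit on the stride lattice; every origin inside the map is
    used and windows are truncated at the boundary, so the whole map is
    spanned whenever stride <= patch (a stride exceeding the patch skips
    cells). ``stride=None`` means the default stride (= patch). With
    ``return_argmax`` the flat padded-plane index of each window's maximum is
    returned too (needed for backpropagation).
    """
    maps = np.asarray(maps, dtype=float)
    H, W = maps.shape[-3], maps.shape[-2]
    ph, pw = patch
    if ph > H or pw > W:
        raise ValueError(f"pool patch {patch} exceeds map ({H}, {W})")
    stride = patch if stride is None else tuple(stride)
    if stride[0] < 1 or stride[1] < 1:
        raise ValueError("stride components must be >= 1")

    Hp, Wp = _pad_for_pool((H, W), patch, stride)
    Hp, Wp = max(Hp, H), max(Wp, W)  # stride > patch pads nothing extra
    pad = [(0, 0)] * (maps.ndim - 3) + [(0, Hp - H), (0, Wp - W), (0, 0)]
    padded = np.pad(maps, pad, constant_values=-np.inf)
    win = sliding_window_view(padded, patch, axis=(-3, -2))
    win = win[..., ::stride[0], ::stride[1], :, :, :]
    # win: (..., nr, nc, T, ph, pw)
    flat = win.reshape(*win.shape[:-2], ph * pw)
    pooled = flat.max(axis=-1)
    if not return_argmax:
        return pooled
    arg = flat.argmax(axis=-1)  # index within the window
    nr, nc = pooled.shape[-3], pooled.shape[-2]
    orow = (np.arange(nr) * stride[0])[:, None, None]
    ocol = (np.arange(nc) * stride[1])[None, :, None]
    rows = orow + arg // pw  # (..., nr, nc, T)
    cols = ocol + arg % pw
    flat_idx = rows * Wp + cols  # index into the padded (Hp, Wp) plane
    return pooled, flat_idx, (Hp, Wp)


def pool_coverage(
    plane: tuple[int, int], patch: tuple[int, int], stride: tuple[int, int]
) -> np.ndarray:
    """Visit counts per input cell under the pooling scheme (brute force).

    Used to check coverage ("the whole input is spanned") and overlap
    (some cell visited more than once iff stride < patch componentwise).
    """
    counts = np.zeros(plane, dtype=int)
    nr, nc = pool_output_shape(plane, stride)
    for i in range(nr):
        for j in range(nc):
            r0, c0 = i * stride[0], j * stride[1]
            counts[r0 : r0 + patch[0], c0 : c0 + patch[1]] += 1
    return counts


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNet:
    """conv -> tanh -> max-pool -> hidden tanh layer -> 2-class softmax."""

    def __init__(self, spec: ModelSpec, cfg: TrainConfig):
        self.spec = spec
        self.cfg = cfg
        H, W, T = spec.input_shape
        kh, kw = spec.patches.conv_patch
        self.map_shape = conv_output_shape((H, W), spec.patches.conv_patch)
        self.pooled_shape = pool_output_shape(self.map_shape, spec.patches.pool_stride)
        n_flat = self.pooled_shape[0] * self.pooled_shape[1] * T

        rng = np.random.default_rng(cfg.seed)

        def init(*shape):
            fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else shape[0]
            bound = 1.0 / np.sqrt(max(fan_in, 1))
            return rng.uniform(-bound, bound, size=shape)

        kshape = (T, kh, kw) if spec.per_slice_kernels else (kh, kw)
        self.Wc = init(*kshape) * np.sqrt(1.0 / (kh * kw))
        self.bc = 0.0
        self.W1 = init(n_flat, cfg.hidden_units)
        self.b1 = np.zeros(cfg.hidden_units)
        self.W2 = init(cfg.hidden_units, 2)
        self.b2 = np.zeros(2)
        self._rng = rng

    # -- forward -----------------------------------------------------------

    def _as_slices(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.spec.input_kind == "2d" and X.ndim == 3:
            X = X[..., None]  # (B, 64, 28) -> (B, 64, 28, 1)
        if X.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"input shape {X.shape[1:]} != expected {self.spec.input_shape}"
            )
        return X

    def _forward(self, X: np.ndarray):
        p = self.spec.patches
        Z = conv_per_slice(X, self.Wc, self.bc)
        A = np.tanh(Z)
        P, argmax, padded_shape = max_pool(
            A, p.pool_patch, p.pool_stride, return_argmax=True
        )
        Pflat = P.reshape(X.shape[0], -1)
        H1 = np.tanh(Pflat @ self.W1 + self.b1)
        logits = H1 @ self.W2 + self.b2
        probs = _softmax(logits)
        return {"X": X, "A": A, "P": P, "argmax": argmax,
                "padded_shape": padded_shape, "Pflat": Pflat,
                "H1": H1, "probs": probs}

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, columns (nontarget, target); rows sum to 1."""
        return self._forward(self._as_slices(X))["probs"]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard 0/1 labels by argmax probability."""
        return self.predict_proba(X).argmax(axis=1)

    # -- backward ----------------------------------------------------------

    def _step(self, X: np.ndarray, y: np.ndarray, lr: float) -> float:
        f = self._forward(X)
        B = X.shape[0]
        probs = f["probs"]
        loss = -np.log(probs[np.arange(B), y] + 1e-12).mean()

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dW2 = f["H1"].T @ dlogits
        db2 = dlogits.sum(axis=0)
        dH1 = dlogits @ self.W2.T
        dZ1 = dH1 * (1.0 - f["H1"] ** 2)
        dW1 = f["Pflat"].T @ dZ1
        db1 = dZ1.sum(axis=0)
        dPflat = dZ1 @ self.W1.T
        dP = dPflat.reshape(f["P"].shape)

        # scatter pooled gradients back to the winning map cells
        Hp, Wp = f["padded_shape"]
        T = self.spec.input_shape[2]
        dApad = np.zeros((B, Hp * Wp, T))
        b_idx = np.arange(B)[:, None, None, None]
        t_idx = np.arange(T)[None, None, None, :]
        np.add.at(dApad, (b_idx, f["argmax"], t_idx), dP)
        mh, mw = self.map_shape
        dA = dApad.reshape(B, Hp, Wp, T)[:, :mh, :mw, :]

        dZ = dA * (1.0 - f["A"] ** 2)
        kh, kw = self.spec.patches.conv_patch
        win = sliding_window_view(f["X"], (kh, kw), axis=(1, 2))
        if self.spec.per_slice_kernels:
            dWc = np.einsum("bijt,bijtkl->tkl", dZ, win)
        else:
            dWc = np.einsum("bijt,bijtkl->kl", dZ, win)
        dbc = dZ.sum()

        self.W2 -= lr * dW2
        self.b2 -= lr * db2
        self.W1 -= lr * dW1
        self.b1 -= lr * db1
        self.Wc -= lr * dWc
        self.bc -= lr * dbc
        return float(loss)

    def fit(self, X: np.ndarray, y: np.ndarray) -> list[float]:
        """Mini-batch SGD; returns the per-epoch mean training loss."""
        X = self._as_slices(X)
        y = np.asarray(y, dtype=np.int64)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(
                "training set contains a single class; both target and "
                "nontarget examples are required"
            )
        n = X.shape[0]
        losses = []
        for _ in range(self.cfg.n_epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, self.cfg.batch_size):
                idx = order[start : start + self.cfg.batch_size]
                epoch_loss += self._step(X[idx], y[idx], self.cfg.learning_rate)
                n_batches += 1
            losses.append(epoch_loss / n_batches)
        return losses


def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
          cfg: TrainConfig | None = None) -> ConvNet:
    """Build and fit one network; deterministic for a fixed cfg.seed."""
    cfg = cfg if cfg is not None else TrainConfig()
    net = ConvNet(spec, cfg)
    net.fit(X, y)
    return net
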