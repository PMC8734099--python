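"""The gene-direction CNN.

Each gene is represented by its expression vector across the samples of a
dataset. The vector is edge-padded to the next perfect square, reshaped
row-major into a single-channel square image, pushed through eight 3x3
same-padding convolutions with ReLU, one 2x2 max pool, an adaptive max
pool to 1x1, and five dense layers. The 1x1 adaptive pool makes the
parameter count independent of the number of samples, which is what lets
one trained model score datasets of any size.

The output head is either 3-class (down-regulated / up-regulated /
neutral, trained with softmax cross-entropy) or 2-class (down / up,
trained with sigmoid cross-entropy on raw scores after the head has been
swapped for fine-tuning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn

DEFAULT_CONV_CHANNELS = (8, 8, 16, 16, 32, 32, 32, 32)
DEFAULT_LINEAR_WIDTHS = (32, 16, 8, 8)  # hidden widths; the head is appended


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    conv_channels are the output channels of the eight convolution layers;
    linear_widths are the output widths of the first four dense layers (the
    fifth, the head, has ``head_arity`` outputs). The first dense layer's
    input width is forced to ``conv_channels[-1]`` by the 1x1 adaptive pool.
    """

    conv_channels: tuple = DEFAULT_CONV_CHANNELS
    linear_widths: tuple = DEFAULT_LINEAR_WIDTHS
    head_arity: int = 3
    seed: int = 0

    def __post_init__(self):
        self.conv_channels = tuple(int(c) for c in self.conv_channels)
        self.linear_widths = tuple(int(w) for w in self.linear_widths)
        if len(self.conv_channels) != 8:
            raise ValueError("conv_channels must list exactly 8 layer widths")
        if len(self.linear_widths) != 4:
            raise ValueError("linear_widths must list exactly 4 hidden widths")
        if any(c < 1 for c in self.conv_channels + self.linear_widths):
            raise ValueError("layer widths must be positive")
        if self.head_arity not in (2, 3):
            raise ValueError("head_arity must be 2 or 3")

    def to_dict(self) -> dict:
        return {
            "conv_channels": list(self.conv_channels),
            "linear_widths": list(self.linear_widths),
            "head_arity": self.head_arity,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            conv_channels=tuple(d["conv_channels"]),
            linear_widths=tuple(d["linear_widths"]),
            head_arity=int(d["head_arity"]),
            seed=int(d.get("seed", 0)),
        )


def reshape_to_2d(vectors: np.ndarray) -> np.ndarray:
    """Pad length-n vectors to the next perfect square and fill row-major.

    Accepts a single vector (n,) or a batch (B, n); returns a channels-last
    batch (B, s, s, 1) with s = ceil(sqrt(n)). Trailing positions repeat
    the last entry (edge padding): injected zeros would look like
    mid-range expression values to the convolution stack and — on small
    datasets, where padding can be a quarter of the grid — visibly skew
    the scores of genes whose signal sits at the end of the vector.
    """
    arr = np.atleast_2d(np.asarray(vectors, dtype=nn.DTYPE))
    if arr.shape[1] == 0:
        raise ValueError("cannot reshape an empty expression vector")
    n = arr.shape[1]
    s = math.isqrt(n)
    if s * s != n:
        s += 1
    m = s * s
    if m > n:
        arr = np.pad(arr, ((0, 0), (0, m - n)), mode="edge")
    return arr.reshape(arr.shape[0], s, s, 1)


class GeneClassifierCNN:
    """Eight-conv, five-dense classifier over per-gene expression vectors."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        self.config = config
        if rng is None:
            rng = np.random.default_rng(config.seed)
        chans = config.conv_channels
        self.convs: list[nn.Conv2d3x3] = []
        in_c = 1
        for out_c in chans:
            self.convs.append(nn.Conv2d3x3(in_c, out_c, rng))
            in_c = out_c
        self.conv_relus = [nn.ReLU() for _ in chans]
        self.midpool = nn.MaxPool2()
        self.adaptive_pool = nn.GlobalMaxPool()
        widths = list(config.linear_widths) + [config.head_arity]
        self.linears: list[nn.Linear] = []
        self.lin_relus = [nn.ReLU() for _ in widths[:-1]]
        in_f = chans[-1]
        for w in widths:
            self.linears.append(nn.Linear(in_f, w, rng))
            in_f = w

    # -- parameter access -------------------------------------------------
    def parameters(self) -> list[nn.Parameter]:
        out = []
        for layer in self.convs + self.linears:
            out.extend(layer.parameters())
        return out

    def backbone_parameters(self) -> list[nn.Parameter]:
        """All parameters except the output head (the fifth dense layer)."""
        out = []
        for layer in self.convs + self.linears[:-1]:
            out.extend(layer.parameters())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, c in enumerate(self.convs):
            state[f"conv{i}.weight"] = c.weight.value
            state[f"conv{i}.bias"] = c.bias.value
        for i, l in enumerate(self.linears):
            state[f"linear{i}.weight"] = l.weight.value
            state[f"linear{i}.bias"] = l.bias.value
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, c in enumerate(self.convs):
            c.weight.value[...] = state[f"conv{i}.weight"]
            c.bias.value[...] = state[f"conv{i}.bias"]
        for i, l in enumerate(self.linears):
            l.weight.value[...] = state[f"linear{i}.weight"]
            l.bias.value[...] = state[f"linear{i}.bias"]

    # -- forward / backward ------------------------------------------------
    def forward_logits(self, vectors: np.ndarray, train: bool = False,
                       check_shapes: bool = False) -> np.ndarray:
        """Raw per-class scores for a batch of expression vectors (B, n)."""
        x = reshape_to_2d(vectors)
        if not np.all(np.isfinite(x)):
            raise ValueError("expression vectors must be finite")
        side = x.shape[1]
        for conv, relu in zip(self.convs, self.conv_relus):
            x = relu.forward(conv.forward(x, train), train)
            if check_shapes:
                assert x.shape[1] == side and x.shape[2] == side
        x = self.midpool.forward(x, train)
        if check_shapes and side >= 2:
            assert x.shape[1] == side // 2 and x.shape[2] == side // 2
        x = self.adaptive_pool.forward(x, train)
        if check_shapes:
            assert x.shape == (x.shape[0], self.config.conv_channels[-1])
        for lin, relu in zip(self.linears[:-1], self.lin_relus):
            x = relu.forward(lin.forward(x, train), train)
        return self.linears[-1].forward(x, train)

    def forward(self, vectors: np.ndarray, check_shapes: bool = False) -> np.ndarray:
        """Class probabilities; rows sum to 1 (softmax over the head)."""
        return nn.softmax(self.forward_logits(vectors, check_shapes=check_shapes))

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.linears[-1].backward(dlogits)
        for lin, relu in zip(reversed(self.linears[:-1]), reversed(self.lin_relus)):
            d = lin.backward(relu.backward(d))
        d = self.adaptive_pool.backward(d)
        d = self.midpool.backward(d)
        for conv, relu in zip(reversed(self.convs), reversed(self.conv_relus)):
            d = conv.backward(relu.backward(d))

    def predict_classes(self, vectors: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Argmax class per gene; exact ties resolve to the lower index."""
        scores = self.predict_scores(vectors, batch_size)
        return np.argmax(scores, axis=1)  # np.argmax returns the first maximum

    def predict_scores(self, vectors: np.ndarray, batch_size: int = 512) -> np.ndarray:
        vectors = np.atleast_2d(vectors)
        out = []
        for i in range(0, vectors.shape[0], batch_size):
            out.append(self.forward_logits(vectors[i:i + batch_size]))
        return np.concatenate(out, axis=0)

    def predict_proba(self, vectors: np.ndarray, batch_size: int = 512) -> np.ndarray:
        return nn.softmax(self.predict_scores(vectors, batch_size))

    # -- head surgery -------------------------------------------------------
    def swap_head(self, new_arity: int, rng: np.random.Generator | None = None) -> "GeneClassifierCNN":
        """Replace the output layer with a freshly initialized one.

        Backbone weights (all convolutions and the first four dense layers)
        are carried over bit-identically. The replacement head starts at
        zero so fine-tuning begins from unbiased scores — by the time the
        head is swapped the backbone produces large, confident features,
        and a random head can start deep in sigmoid saturation that a
        short low-learning-rate fine-tune cannot escape.
        """
        if new_arity not in (2, 3):
            raise ValueError("head arity must be 2 or 3")
        cfg = ModelConfig(
            conv_channels=self.config.conv_channels,
            linear_widths=self.config.linear_widths,
            head_arity=new_arity,
            seed=self.config.seed,
        )
        new = GeneClassifierCNN(cfg, rng=np.random.default_rng(0))
        state = dict(self.state_arrays())
        head = len(self.linears) - 1
        in_f = self.linears[-1].in_features
        state[f"linear{head}.weight"] = np.zeros((new_arity, in_f), dtype=nn.DTYPE)
        state[f"linear{head}.bias"] = np.zeros(new_arity, dtype=nn.DTYPE)
        new.load_state_arrays(state)
        return new
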