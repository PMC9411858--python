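"""The coordinate-regression network: one-hot sequence in, 140 x 15 coordinates out.

The architecture follows the published description: a first 1-D ResNet with
a large kernel (25) over the 22-channel one-hot input, a width-1 convolution
up to 140 channels, a second ResNet of kernel-5 blocks cycling through the
dilation values (1, 2, 4, 8, 16), a 25% dropout layer, and two width-1
projections (to 70, then to 15 channels, no final activation since
coordinates are unbounded). Block counts and widths are configurable; the
defaults land near the published ~2M trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .structure_io import BackboneStructure, Residue

MAX_LEN = 140
N_CHANNELS = 22
N_COORDS = 15
REQUIRED_DILATIONS = (1, 2, 4, 8, 16)
CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    max_len: int = MAX_LEN
    in_channels: int = N_CHANNELS
    resnet1_kernel: int = 25
    resnet1_blocks: int = 3
    resnet1_channels: int = 64
    mid_channels: int = 140
    resnet2_kernel: int = 5
    dilations: tuple[int, ...] = REQUIRED_DILATIONS
    resnet2_blocks_per_dilation: int = 1
    dropout: float = 0.25
    head_channels: tuple[int, int] = (70, 15)
    # fixed scalar applied after the head: coordinates span tens of Angstrom
    # while Adam moves each weight by at most lr per step, so an unscaled
    # near-zero-initialized head needs O(extent / lr) steps just to reach the
    # right magnitude. The gain rescales the optimization geometry; it is a
    # units choice, not a learned parameter.
    output_gain: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if tuple(self.dilations) != REQUIRED_DILATIONS:
            raise ValueError(f"dilations must be {REQUIRED_DILATIONS}")
        if self.head_channels[-1] != N_COORDS:
            raise ValueError("final output channel count must be 15")
        if self.max_len != MAX_LEN or self.in_channels != N_CHANNELS:
            raise ValueError("input geometry is fixed at 140 x 22")

    @staticmethod
    def small(seed: int = 0) -> "ModelConfig":
        """A reduced-width configuration for desk-scale experiments and tests.

        Dropout is disabled: at a few hundred training examples the
        regularization buys nothing and its activation noise, amplified by
        the output gain, puts a floor under the coordinate error.
        """
        return ModelConfig(resnet1_channels=24, resnet1_blocks=2, mid_channels=40,
                           head_channels=(32, 15), dropout=0.0, seed=seed)


class CoordRegressionNet:
    """Dual 1-D ResNet mapping (B, 140, 22) one-hot matrices to (B, 140, 15) coordinates."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, mid = config.resnet1_channels, config.mid_channels
        layers: list[nn.Layer] = [
            nn.Conv1d(config.in_channels, c1, config.resnet1_kernel, rng=rng, name="stem"),
        ]
        for i in range(config.resnet1_blocks):
            layers.append(nn.ResidualBlock(c1, config.resnet1_kernel, rng=rng,
                                           name=f"res1.{i}"))
        layers.append(nn.Conv1d(c1, mid, 1, rng=rng, name="transition"))
        for r in range(config.resnet2_blocks_per_dilation):
            for d in config.dilations:
                layers.append(nn.ResidualBlock(mid, config.resnet2_kernel, dilation=d,
                                               rng=rng, name=f"res2.{r}.d{d}"))
        layers += [
            nn.BatchNorm1d(mid, name="final_bn"),
            nn.ReLU(),
            nn.Dropout(config.dropout),
            nn.Conv1d(mid, config.head_channels[0], 1, rng=rng, name="head1"),
            nn.ReLU(),
            nn.Conv1d(config.head_channels[0], config.head_channels[1], 1, rng=rng,
                      name="head2"),
        ]
        # zero-init the final projection: predictions start at the coordinate
        # origin instead of amplified noise (standard for regression heads)
        layers[-1].weight.value[...] = 0.0
        self.net = nn.Sequential(layers)

    # -- parameter plumbing ------------------------------------------------
    def parameters(self) -> list[nn.Parameter]:
        return self.net.params()

    @property
    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def get_state(self) -> list[np.ndarray]:
        """Trained parameters followed by buffers (batch-norm running stats)."""
        return ([p.value.copy() for p in self.parameters()]
                + [b.copy() for b in self.net.buffers()])

    def set_state(self, state: list[np.ndarray]) -> None:
        own = self.parameters()
        buffers = self.net.buffers()
        if len(own) + len(buffers) != len(state):
            raise ValueError("checkpoint/architecture mismatch: state length differs")
        for p, v in zip(own, state):
            if p.value.shape != v.shape:
                raise ValueError(f"checkpoint/architecture mismatch at {p.name}")
            p.value[...] = v
        for b, v in zip(buffers, state[len(own):]):
            b[...] = v

    # -- forward/backward --------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        if x.shape[1:] != (self.config.max_len, self.config.in_channels):
            raise ValueError(f"expected input of shape (B, {self.config.max_len}, "
                             f"{self.config.in_channels}), got {x.shape}")
        out = self.net.forward(x.transpose(0, 2, 1), training, rng).transpose(0, 2, 1)
        out = out * self.config.output_gain
        return out[0] if squeeze else out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if dout.ndim == 2:
            dout = dout[None]
        dout = dout * self.config.output_gain
        return self.net.backward(dout.transpose(0, 2, 1)).transpose(0, 2, 1)


def build_model(config: ModelConfig | None = None) -> CoordRegressionNet:
    return CoordRegressionNet(config or ModelConfig())


def predict_coords(model: CoordRegressionNet, inputs: np.ndarray,
                   inference_mode: bool = True, rng=None) -> np.ndarray:
    """Run the network; with ``inference_mode`` the output is deterministic."""
    return model.forward(inputs, training=not inference_mode, rng=rng)


def prediction_to_structure(pred: np.ndarray, sequence: str, chain_id: str = "H",
                            source_id: str = "model") -> BackboneStructure:
    """Unpad a (140, 15) coordinate matrix into a BackboneStructure.

    The 15 components per row are the N, CA, C, O, CB triples in that order;
    glycine rows drop the CB.
    """
    pred = np.asarray(pred, dtype=float)
    if pred.shape != (MAX_LEN, N_COORDS):
        raise ValueError(f"prediction must be ({MAX_LEN}, {N_COORDS})")
    if len(sequence) > MAX_LEN:
        raise ValueError("sequence longer than the padded frame")
    atoms = ("N", "CA", "C", "O", "CB")
    residues = []
    for i, aa in enumerate(sequence):
        triples = pred[i].reshape(5, 3)
        coords = {name: triples[j].copy() for j, name in enumerate(atoms)}
        cb_present = aa != "G"
        if not cb_present:
            coords.pop("CB")
        residues.append(Residue(i, aa, coords, cb_present))
    return BackboneStructure(chain_id, residues, source_id)


def ca_mirror_fraction(structure: BackboneStructure) -> float:
    """Chirality diagnostic: fraction of CA virtual dihedrals with negative sign.

    Native protein backbones have predominantly positive consecutive-CA
    virtual dihedrals; a mirror-image prediction flips the distribution.
    Purely diagnostic — no correction is applied.
    """
    ca = structure.ca_coords()
    if len(ca) < 4:
        raise ValueError("need at least 4 residues")
    b1, b2, b3 = ca[1:-2] - ca[:-3], ca[2:-1] - ca[1:-2], ca[3:] - ca[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    dihedrals = np.arctan2((m1 * n2).sum(1), (n1 * n2).sum(1))
    return float(np.mean(dihedrals < 0))


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: CoordRegressionNet, path: str,
                    reference_id: str = "") -> None:
    """Write parameters + config + reference-structure id with a versioned header."""
    header = json.dumps({
        "format": "vhfold-checkpoint",
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "reference_id": reference_id,
    })
    arrays = {f"state_{i}": v for i, v in enumerate(model.get_state())}
    np.savez(path, header=np.array(header), **arrays)


def load_checkpoint(path: str) -> tuple[CoordRegressionNet, str]:
    """Load a checkpoint; returns (model, reference_id)."""
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        if header.get("format") != "vhfold-checkpoint":
            raise ValueError("not a vhfold checkpoint")
        if header["version"] > CHECKPOINT_VERSION:
            raise ValueError("checkpoint written by a newer version")
        cfg = header["config"]
        cfg["dilations"] = tuple(cfg["dilations"])
        cfg["head_channels"] = tuple(cfg["head_channels"])
        model = CoordRegressionNet(ModelConfig(**cfg))
        n_state = len(model.parameters()) + len(model.net.buffers())
        state = [data[f"state_{i}"] for i in range(n_state)]
    model.set_state(state)
    return model, header["reference_id"]
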