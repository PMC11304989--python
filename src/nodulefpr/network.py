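"""The false-positive-reduction classifier: 3 conv blocks + a dense block.

Architecture per block: two same-padded 3×3×3 convolutions each followed by
a leaky ReLU, then 2× 3D max pooling and dropout (rate 0.3).  The dense
block applies global 3D average pooling, two fully connected layers of 128
nodes (leaky ReLU, dropout 0.9 during training) and a single-logit sigmoid
head giving the nodule probability.  With the default input of
(15, 48, 48) voxels, pooling uses floor division: z 15 → 7 → 3 → 1,
in-plane 48 → 24 → 12 → 6.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from nodulefpr import nn

__all__ = ["NetworkConfig", "Network", "build_network", "predict",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class NetworkConfig:
    """Hyperparameters of the classifier.

    ``conv_kernels`` are the filter counts of the three blocks; the leaky
    slope is fixed at 0.01 (the activation family is specified, its slope is
    a free constant).  The confidence of the single-logit head is
    max(p, 1 − p).
    """

    conv_kernels: Tuple[int, int, int] = (32, 64, 128)
    convs_per_block: int = 2
    leaky_slope: float = 0.01
    conv_dropout: float = 0.3
    fc_nodes: Tuple[int, int] = (128, 128)
    fc_dropout: float = 0.9
    input_shape: Tuple[int, int, int] = (15, 48, 48)

    def __post_init__(self) -> None:
        if len(self.conv_kernels) != 3:
            raise ValueError("conv_kernels must list three block widths")
        for rate in (self.conv_dropout, self.fc_dropout):
            if not 0.0 <= rate < 1.0:
                raise ValueError("dropout rates must lie in [0, 1)")


class Network:
    """The classifier: a layer stack plus a sigmoid head over one logit."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = int(seed)
        d, h, w = cfg.input_shape
        for name, extent in zip("zyx", (d, h, w)):
            if extent // 2 // 2 // 2 < 1:
                raise ValueError(
                    f"input axis {name} (extent {extent}) cannot be max-pooled "
                    f"three times"
                )
        rng = np.random.default_rng(self.seed)
        layers: List[nn.Layer] = []
        in_ch = 1
        for width in cfg.conv_kernels:
            for _ in range(cfg.convs_per_block):
                layers.append(nn.Conv3d(in_ch, width, rng, cfg.leaky_slope))
                layers.append(nn.LeakyReLU(cfg.leaky_slope))
                in_ch = width
            layers.append(nn.MaxPool3d())
            layers.append(nn.Dropout(cfg.conv_dropout))
        layers.append(nn.GlobalAvgPool())
        in_feat = cfg.conv_kernels[-1]
        for width in cfg.fc_nodes:
            layers.append(nn.Dense(in_feat, width, rng, cfg.leaky_slope))
            layers.append(nn.LeakyReLU(cfg.leaky_slope))
            layers.append(nn.Dropout(cfg.fc_dropout))
            in_feat = width
        layers.append(nn.Dense(in_feat, 1, rng, cfg.leaky_slope))  # sigmoid head
        self.model = nn.Sequential(layers)
        self._head_index = len(layers) - 1

    # -- forward ----------------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False,
                       rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Logits for a batch shaped (n, z, y, x) or (n, 1, z, y, x)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[:, None]
        if x.shape[2:] != tuple(self.cfg.input_shape):
            raise ValueError(
                f"batch spatial shape {x.shape[2:]} does not match the "
                f"network input shape {tuple(self.cfg.input_shape)}"
            )
        return self.model.forward(x, train=train, rng=rng)[:, 0]

    def predict(self, rois: Sequence[np.ndarray] | np.ndarray,
                batch_size: int = 32) -> np.ndarray:
        """Nodule probabilities in (0, 1), one per ROI, order preserved;
        dropout inactive."""
        patches = [np.asarray(r, dtype=np.float32) for r in rois]
        if len(patches) == 0:
            return np.zeros(0, dtype=np.float64)
        scores = []
        for start in range(0, len(patches), batch_size):
            batch = np.stack(patches[start:start + batch_size])
            scores.append(nn.sigmoid(self.forward_logits(batch, train=False)))
        return np.concatenate(scores)

    # -- bookkeeping ------------------------------------------------------

    def layer_census(self) -> Dict[str, int]:
        """Count layers by role (the scalar sigmoid head is reported
        separately from the two hidden fully connected layers)."""
        census = {"conv": 0, "max_pool": 0, "avg_pool": 0,
                  "fully_connected": 0, "output_head": 0, "dropout": 0}
        for i, layer in enumerate(self.model.layers):
            if isinstance(layer, nn.Conv3d):
                census["conv"] += 1
            elif isinstance(layer, nn.MaxPool3d):
                census["max_pool"] += 1
            elif isinstance(layer, nn.GlobalAvgPool):
                census["avg_pool"] += 1
            elif isinstance(layer, nn.Dropout):
                census["dropout"] += 1
            elif isinstance(layer, nn.Dense):
                if i == self._head_index:
                    census["output_head"] += 1
                else:
                    census["fully_connected"] += 1
        return census

    def params(self) -> List[Dict]:
        return self.model.params()

    def zero_grad(self) -> None:
        self.model.zero_grad()


def build_network(cfg: Optional[NetworkConfig] = None, seed: int = 0) -> Network:
    """Build the classifier with seeded weight initialisation."""
    return Network(cfg or NetworkConfig(), seed=seed)


def predict(net: Network, rois: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`Network.predict`."""
    return net.predict(rois)


def save_checkpoint(net: Network, path: os.PathLike | str) -> None:
    """Persist config + weights + init seed (npz with an embedded JSON header)."""
    cfg = net.cfg
    header = json.dumps({
        "conv_kernels": list(cfg.conv_kernels),
        "convs_per_block": cfg.convs_per_block,
        "leaky_slope": cfg.leaky_slope,
        "conv_dropout": cfg.conv_dropout,
        "fc_nodes": list(cfg.fc_nodes),
        "fc_dropout": cfg.fc_dropout,
        "input_shape": list(cfg.input_shape),
        "seed": net.seed,
    })
    arrays = net.model.state_arrays()
    np.savez(path, __config__=np.frombuffer(header.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: os.PathLike | str) -> Network:
    with np.load(path) as data:
        header = json.loads(bytes(data["__config__"]).decode())
        cfg = NetworkConfig(
            conv_kernels=tuple(header["conv_kernels"]),
            convs_per_block=header["convs_per_block"],
            leaky_slope=header["leaky_slope"],
            conv_dropout=header["conv_dropout"],
            fc_nodes=tuple(header["fc_nodes"]),
            fc_dropout=header["fc_dropout"],
            input_shape=tuple(header["input_shape"]),
        )
        net = Network(cfg, seed=header["seed"])
        net.model.load_state_arrays({k: data[k] for k in data.files
                                     if k != "__config__"})
    return net
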