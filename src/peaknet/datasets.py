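"""HDF5 persistence for encoded datasets and model checkpoints.

A dataset container holds named arrays — ``sequences`` (N, 4, L),
``targets`` (N, T), the three split index vectors, cell labels — plus
the split seed as an attribute.  A checkpoint is a single portable HDF5
file with the architecture as a JSON attribute and one dataset per
parameter array (batch-norm running moments included), so a model can be
rebuilt exactly anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from .nn import ArchitectureSpec, Network
from .peaks import DatasetSplit


@dataclass
class EncodedDataset:
    X: np.ndarray             # (N, 4, L) one-hot
    Y: np.ndarray             # (N, T) binary
    split: DatasetSplit
    cell_names: list


def save_dataset(path, X, Y, split: DatasetSplit, cell_names, attrs=None):
    with h5py.File(path, "w") as h5:
        h5.create_dataset("sequences", data=np.asarray(X, dtype=np.float32),
                          compression="gzip")
        h5.create_dataset("targets", data=np.asarray(Y, dtype=np.uint8),
                          compression="gzip")
        h5.create_dataset("train_idx", data=np.asarray(split.train_idx, dtype=np.int64))
        h5.create_dataset("valid_idx", data=np.asarray(split.valid_idx, dtype=np.int64))
        h5.create_dataset("test_idx", data=np.asarray(split.test_idx, dtype=np.int64))
        h5.create_dataset(
            "cell_names",
            data=np.array([str(c) for c in cell_names], dtype=h5py.string_dtype()),
        )
        h5.attrs["split_seed"] = split.seed
        for k, v in (attrs or {}).items():
            h5.attrs[k] = v


def load_dataset(path) -> EncodedDataset:
    with h5py.File(path, "r") as h5:
        split = DatasetSplit(
            train_idx=h5["train_idx"][:],
            valid_idx=h5["valid_idx"][:],
            test_idx=h5["test_idx"][:],
            seed=int(h5.attrs.get("split_seed", -1)),
        )
        return EncodedDataset(
            X=h5["sequences"][:],
            Y=h5["targets"][:],
            split=split,
            cell_names=[c.decode() if isinstance(c, bytes) else str(c)
                        for c in h5["cell_names"][:]],
        )


def save_checkpoint(path, network: Network, cell_names=None, meta=None):
    spec = network.spec
    arch = {
        "n_targets": spec.n_targets,
        "input_length": spec.input_length,
        "conv_layers": [list(c) for c in spec.conv_layers],
        "fc_layers": list(spec.fc_layers),
        "dropout_rates": list(spec.dropout_rates),
    }
    with h5py.File(path, "w") as h5:
        h5.attrs["architecture"] = json.dumps(arch)
        h5.attrs["dtype"] = np.dtype(network.dtype).name
        if cell_names is not None:
            h5.create_dataset(
                "cell_names",
                data=np.array([str(c) for c in cell_names], dtype=h5py.string_dtype()),
            )
        grp = h5.create_group("state")
        for key, arr in network.get_state().items():
            grp.create_dataset(key, data=arr)
        for k, v in (meta or {}).items():
            h5.attrs[k] = v


def load_checkpoint(path):
    """Rebuild the network (and cell names, if stored) from a checkpoint."""
    with h5py.File(path, "r") as h5:
        arch = json.loads(h5.attrs["architecture"])
        spec = ArchitectureSpec(
            n_targets=arch["n_targets"],
            input_length=arch["input_length"],
            conv_layers=tuple(tuple(c) for c in arch["conv_layers"]),
            fc_layers=tuple(arch["fc_layers"]),
            dropout_rates=tuple(arch["dropout_rates"]),
        )
        network = Network(spec, seed=0, dtype=np.dtype(h5.attrs["dtype"]).type)
        state = {}
        def _collect(name, obj):
            if isinstance(obj, h5py.Dataset):
                state[name] = obj[:]
        h5["state"].visititems(_collect)
        network.set_state(state)
        cells = None
        if "cell_names" in h5:
            cells = [c.decode() if isinstance(c, bytes) else str(c)
                     for c in h5["cell_names"][:]]
    return network, cells
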