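"""HDF5 checkpoints: parameters plus an embedded JSON architecture descriptor.

Layout: ``/forward/w{n}``, ``/forward/b{n}``, ``/backward/w{n}``,
``/readout/w_out`` with the architecture JSON stored as a file attribute.
Loading round-trips bit-exactly (float64 datasets, no compression filters
that would alter values).
"""

from __future__ import annotations

import h5py
import numpy as np

from .model import ArchitectureSpec, Parameters

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(path, params: Parameters, arch: ArchitectureSpec) -> None:
    params.validate(arch)
    with h5py.File(path, "w") as f:
        f.attrs["architecture"] = arch.to_json()
        fw = f.create_group("forward")
        for n, w in enumerate(params.weights, start=1):
            fw.create_dataset(f"w{n}", data=w)
        for n, b in enumerate(params.biases, start=1):
            if b is not None:
                fw.create_dataset(f"b{n}", data=b)
        if params.backward_weights is not None:
            bw = f.create_group("backward")
            for n, w in enumerate(params.backward_weights, start=1):
                if w is not None:
                    bw.create_dataset(f"w{n}", data=w)
        if params.w_out is not None:
            f.create_group("readout").create_dataset("w_out", data=params.w_out)


def load_checkpoint(path) -> tuple[ArchitectureSpec, Parameters]:
    with h5py.File(path, "r") as f:
        arch = ArchitectureSpec.from_json(f.attrs["architecture"])
        weights = [np.asarray(f["forward"][f"w{n}"]) for n in range(1, arch.n_tot + 1)]
        biases = [
            np.asarray(f["forward"][f"b{n}"]) if f"b{n}" in f["forward"] else None
            for n in range(1, arch.n_tot + 1)
        ]
        backward = None
        if "backward" in f:
            backward = [
                np.asarray(f["backward"][f"w{n}"]) if f"w{n}" in f["backward"] else None
                for n in range(1, arch.n_tot + 1)
            ]
        w_out = np.asarray(f["readout"]["w_out"]) if "readout" in f else None
    params = Parameters(weights=weights, biases=biases, backward_weights=backward, w_out=w_out)
    params.validate(arch)
    return arch, params
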