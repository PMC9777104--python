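"""Single-file checkpoints: parameters + buffers + a JSON config header.

The file is a ``.npz`` archive whose ``__meta__`` entry holds a JSON string
with a format version and an arbitrary config dict; all other entries are
the model's ``state_dict`` arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

FORMAT_VERSION = 1

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(path, module, config: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"format_version": FORMAT_VERSION, "config": config})
    state = module.state_dict()
    arrays = {f"param:{k}": v for k, v in state.items()}
    arrays["__meta__"] = np.frombuffer(meta.encode("utf-8"), dtype=np.uint8)
    if path.suffix == ".npz":
        np.savez(path, **arrays)
    else:
        # numpy always appends .npz; write there, then move over the target
        tmp = path.with_name(path.name + ".npz")
        np.savez(tmp, **arrays)
        tmp.replace(path)


def load_checkpoint(path) -> tuple[dict, dict]:
    """Return ``(state_dict, config)`` from a checkpoint file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode("utf-8"))
        if meta.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format: {meta.get('format_version')}")
        state = {k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")}
    return state, meta["config"]
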