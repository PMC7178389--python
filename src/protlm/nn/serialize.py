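"""Checkpoints: a single .npz archive carrying all arrays plus a JSON manifest
(config, vocabulary, epoch) under the reserved key ``__manifest__``."""

from __future__ import annotations

import json

import numpy as np

MANIFEST_KEY = "__manifest__"


def save_checkpoint(path, arrays: dict[str, np.ndarray], manifest: dict):
    payload = dict(arrays)
    payload[MANIFEST_KEY] = np.frombuffer(
        json.dumps(manifest, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as data:
        manifest = json.loads(bytes(data[MANIFEST_KEY]).decode())
        arrays = {k: data[k] for k in data.files if k != MANIFEST_KEY}
    return arrays, manifest
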