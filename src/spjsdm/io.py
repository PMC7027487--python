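"""Posterior persistence: long-format CSV per parameter block + JSON metadata.

Draws round-trip losslessly (Python float repr) through
``write_posterior`` / ``read_posterior``; no binary formats are used.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .sampler import PosteriorSamples

__all__ = ["write_posterior", "read_posterior"]

# block name -> (attribute, index label per trailing axis)
_BLOCKS = {
    "beta": ("beta", ("covariate", "species")),
    "gamma": ("gamma", ("covariate", "trait")),
    "lambda": ("lam", ("factor", "species")),
    "eta": ("eta", ("site", "factor")),
    "alpha_index": ("alpha_index", ("factor",)),
    "phi": ("phi", ("factor", "species")),
    "delta": ("delta", ("factor",)),
    "sigma2": ("sigma2", ("species",)),
    "Z": ("Z", ("site", "species")),
}


def _long_frame(arr: np.ndarray, labels) -> pd.DataFrame:
    n_draws = arr.shape[0]
    dims = arr.shape[1:]
    idx = np.indices((n_draws, *dims)).reshape(1 + len(dims), -1)
    cols = {"iteration": idx[0]}
    for d, lab in enumerate(labels):
        cols[lab] = idx[1 + d]
    cols["value"] = arr.reshape(-1)
    return pd.DataFrame(cols)


def write_posterior(samples: PosteriorSamples, outdir) -> dict:
    """Write one CSV per parameter block plus ``meta.json``; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for block, (attr, labels) in _BLOCKS.items():
        arr = getattr(samples, attr)
        path = os.path.join(outdir, f"{block}.csv")
        # %.17g + round_trip parsing keeps draws bit-identical through CSV
        _long_frame(arr, labels).to_csv(path, index=False, float_format="%.17g")
        paths[block] = path
    meta = dict(samples.meta)
    meta["n_retained"] = samples.n_draws
    meta["shapes"] = {
        block: list(getattr(samples, attr).shape)
        for block, (attr, _) in _BLOCKS.items()
    }
    mpath = os.path.join(outdir, "meta.json")
    with open(mpath, "w") as fh:
        json.dump(meta, fh, indent=2)
    paths["meta"] = mpath
    return paths


def read_posterior(outdir) -> PosteriorSamples:
    """Reconstruct :class:`PosteriorSamples` written by ``write_posterior``."""
    with open(os.path.join(outdir, "meta.json")) as fh:
        meta = json.load(fh)
    shapes = meta.pop("shapes")
    n_retained = meta.pop("n_retained")
    arrays = {}
    for block, (attr, labels) in _BLOCKS.items():
        shape = tuple(shapes[block])
        df = pd.read_csv(
            os.path.join(outdir, f"{block}.csv"), float_precision="round_trip"
        )
        arr = np.zeros(shape)
        if len(df):
            index = tuple(
                df[lab].to_numpy() for lab in ("iteration", *labels)
            )
            arr[index] = df["value"].to_numpy()
        if block == "alpha_index":
            arr = arr.astype(int)
        arrays[attr] = arr
    out = PosteriorSamples(meta=meta, **arrays)
    assert out.n_draws == n_retained
    return out
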