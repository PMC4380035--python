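"""Versioned, human-readable (JSON) checkpoints of an analysis state.

A checkpoint captures everything needed to rebuild a `TreeLikelihood` to
the same total log-likelihood: the tree (Newick with full-precision branch
lengths), every partition's model parameters (frequencies, linked class
rates, Gamma shape, PSR rates and assignments), the scaling mode, the run
seed, and optimizer progress markers.  Restoring and continuing is
deterministic because every optimisation step is deterministic given the
restored state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .likelihood import TreeLikelihood
from .tree import parse_newick, write_newick

CHECKPOINT_VERSION = 1


class CheckpointError(ValueError):
    pass


def capture_state(tl: TreeLikelihood, seed: int | None = None,
                  progress: dict | None = None,
                  logl: float | None = None) -> dict:
    """Serialisable snapshot of tree, models, and optimizer progress."""
    partitions = []
    for model, ps in zip(tl.models, tl.parts):
        entry: dict = {
            "model": str(model.spec),
            "frequencies": model.subst.freqs.tolist(),
            "freq_mode": model.freq_mode,
        }
        if model.subst.linkage is not None:
            entry["linkage"] = model.subst.linkage.rgs
            entry["class_rates"] = model.subst.class_rates.tolist()
        if model.het.mode == "GAMMA":
            entry["alpha"] = model.het.alpha
            entry["gamma_categories"] = model.het.n_categories
        elif model.het.mode == "PSR":
            entry["psr_rates"] = model.het.rates().tolist()
            entry["psr_assign"] = ps.psr_assign.tolist()
        partitions.append(entry)
    return {
        "version": CHECKPOINT_VERSION,
        "newick": write_newick(tl.tree),
        "scaling": tl.scaling,
        "seed": seed,
        "partitions": partitions,
        "progress": progress or {},
        "logl": logl,
    }


def save_checkpoint(path: str | Path, state: dict) -> None:
    Path(path).write_text(json.dumps(state, indent=1) + "\n")


def load_checkpoint(path: str | Path) -> dict:
    try:
        state = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from None
    if state.get("version") != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"unsupported checkpoint version {state.get('version')!r}")
    return state


def apply_state(tl: TreeLikelihood, state: dict) -> None:
    """Restore model parameters from a snapshot onto a freshly built
    evaluator (whose tree must already be the checkpointed tree)."""
    if len(state["partitions"]) != len(tl.models):
        raise CheckpointError("checkpoint partition count mismatch")
    for model, ps, entry in zip(tl.models, tl.parts, state["partitions"]):
        if str(model.spec) != entry["model"]:
            raise CheckpointError(
                f"checkpoint model {entry['model']!r} does not match"
                f" configured {str(model.spec)!r}")
        model.subst.set_frequencies(np.asarray(entry["frequencies"]))
        if "class_rates" in entry:
            model.subst.set_class_rates(np.asarray(entry["class_rates"]))
        if "alpha" in entry:
            model.het.set_alpha(entry["alpha"])
        if "psr_rates" in entry:
            model.het.psr_rates = np.asarray(entry["psr_rates"])
            ps.psr_assign = np.asarray(entry["psr_assign"], dtype=np.int64)


def restore(tl_factory, state: dict) -> TreeLikelihood:
    """Rebuild an evaluator from a checkpoint: ``tl_factory(tree)`` builds
    the evaluator for the checkpointed tree; parameters are then applied."""
    tree = parse_newick(state["newick"])
    tl = tl_factory(tree)
    apply_state(tl, state)
    return tl
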