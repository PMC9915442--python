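"""Recovery metrics against the synthetic truth manifest."""

from __future__ import annotations

import pandas as pd

from .simulate import TruthManifest


def dmr_recovery(dmrs: pd.DataFrame, manifest: TruthManifest, context: str | None = None) -> dict:
    """Sensitivity (planted bins called with the correct direction) and
    empirical FDR (called bins that were not planted) of a DMR call set.

    ``dmrs`` is the call_dmrs output (is_dmr/direction columns).
    """
    planted = manifest.planted_dmrs
    called = dmrs[dmrs["is_dmr"]]
    if context is not None:
        planted = planted[planted["context"] == context]
        called = called[called["context"] == context]
    planted_keys = {(r.chrom, r.bin_start): r.direction for r in planted.itertuples()}
    called_keys = {(r.chrom, r.start): r.direction for r in called.itertuples()}
    hits = sum(
        1 for key, direction in planted_keys.items() if called_keys.get(key) == direction
    )
    false = sum(1 for key in called_keys if key not in planted_keys)
    return {
        "n_planted": len(planted_keys),
        "n_called": len(called_keys),
        "n_recovered": hits,
        "sensitivity": hits / len(planted_keys) if planted_keys else float("nan"),
        "n_false": false,
        "fdr": false / len(called_keys) if called_keys else 0.0,
    }


def deg_recovery(degs: pd.DataFrame, manifest: TruthManifest, genotype: str) -> dict:
    """Planted-DEG sensitivity and false-call rate among unplanted genes."""
    planted = manifest.planted_degs
    planted = set(planted.loc[planted["genotype"] == genotype, "gene_id"])
    called = set(degs.index[degs["is_deg"]])
    all_genes = set(degs.index)
    unplanted = all_genes - planted
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "n_recovered": len(called & planted),
        "sensitivity": len(called & planted) / len(planted) if planted else float("nan"),
        "n_false": len(called - planted),
        "false_call_rate": len(called - planted) / len(unplanted) if unplanted else 0.0,
    }
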