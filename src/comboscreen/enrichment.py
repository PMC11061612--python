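"""Enrichment of active combinations in mechanism (pathway-pair) categories.

Given per (combination, cell line) activity calls and a mechanism category
per combination (e.g. "cell death + DDR"), the observed enrichment for
synergy in category *c* is ``Es = nc / Nc`` — the fraction of the
category's pairs that are active.  The null baseline redistributes the
``n`` active labels uniformly at random over all pairs (a permutation
null); with ``nb`` the mean active count per category over the bootstrap
replicates, ``Er = nb / Nc`` is the enrichment by random, and a category
is *enriched* when ``Es > Er``.  An empirical p-value (fraction of
replicates whose random count reaches the observed one) is reported as a
supplementary measure of how extreme the observed count is under the null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["enrichment_over_random"]


def enrichment_over_random(
    activity_calls: pd.DataFrame,
    category_labels: pd.DataFrame | dict,
    n_boot: int = 10,
    seed: int = 0,
    unit: str = "pair",
) -> pd.DataFrame:
    """Per-category Es/Er enrichment of active pairs over random assignment.

    Parameters
    ----------
    activity_calls
        Columns ``combo_id``, ``cell_line``, ``active`` (bool).
    category_labels
        ``combo_id -> category`` mapping (dict or frame with those columns).
    n_boot
        Number of random redistributions of the active labels (default 10).
    unit
        ``"pair"`` counts combination–cell-line pairs (default);
        ``"combination"`` collapses to one unit per combination (active if
        active in any cell line).
    """
    if isinstance(category_labels, pd.DataFrame):
        cat_map = category_labels.set_index("combo_id")["category"].to_dict()
    else:
        cat_map = dict(category_labels)

    calls = activity_calls
    if unit == "combination":
        calls = (
            calls.groupby("combo_id")["active"].any().reset_index()
        )
    elif unit != "pair":
        raise ValueError(f"unknown counting unit {unit!r}")

    missing = set(calls["combo_id"]) - set(cat_map)
    if missing:
        raise ValueError(f"combinations without category: {sorted(missing)}")
    categories = calls["combo_id"].map(cat_map).to_numpy()
    active = calls["active"].to_numpy(dtype=bool)
    n_total = active.size
    n_active = int(active.sum())

    cats = np.unique(categories)
    cat_index = {c: i for i, c in enumerate(cats)}
    cat_codes = np.fromiter((cat_index[c] for c in categories), dtype=int)
    n_c = np.bincount(cat_codes, minlength=cats.size)  # Nc per category
    obs = np.bincount(cat_codes[active], minlength=cats.size)  # nc per category

    rng = np.random.default_rng(seed)
    boot_counts = np.zeros((n_boot, cats.size), dtype=int)
    for b in range(n_boot):
        hit = rng.choice(n_total, size=n_active, replace=False)
        boot_counts[b] = np.bincount(cat_codes[hit], minlength=cats.size)
    nb = boot_counts.mean(axis=0)
    p_emp = (boot_counts >= obs).mean(axis=0)

    return pd.DataFrame(
        {
            "category": cats,
            "Nc": n_c,
            "nc": obs,
            "Es": obs / n_c,
            "nb": nb,
            "Er": nb / n_c,
            "enriched": obs / n_c > nb / n_c,
            "p_empirical": p_emp,
        }
    )
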