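"""Shared fixtures: tiny deterministic panels and record builders.

All fixtures are generated programmatically; nothing binary is stored.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from omicsmr.sumstats import AssocRecord, LdPanel, QtlRecord, Variant


def make_variant(vid="rs1", chrom="1", pos=1_000_000, a1="A", a2="G", eaf=0.3):
    return Variant(id=vid, chrom=chrom, pos=pos, a1=a1, a2=a2, eaf=eaf)


def make_assoc(vid="rs1", beta=0.1, se=0.02, p=None, n=1980, **vkw):
    """AssocRecord with p derived from beta/se unless given (avoids the
    consistency warning)."""
    if p is None:
        p = float(2 * stats.norm.sf(abs(beta / se)))
        p = min(max(p, 1e-300), 1.0)
    return AssocRecord(variant=make_variant(vid, **vkw), beta=beta, se=se, p=p, n=n)


def make_qtl(vid="rs1", gene="GENE1", probe=None, layer="eQTL",
             probe_pos=2_000_000, **kw):
    return QtlRecord(
        assoc=make_assoc(vid, **kw),
        probe_id=probe or gene,
        gene=gene,
        layer=layer,
        probe_pos=probe_pos,
    )


def make_panel(columns: dict, variant_meta: dict | None = None,
               n_individuals=200, seed=0):
    """LdPanel from explicit dosage columns; unspecified ids get independent
    binomial draws at frequency 0.3."""
    variant_meta = variant_meta or {}
    rng = np.random.default_rng(seed)
    explicit = [np.asarray(c) for c in columns.values() if c is not None]
    if explicit:
        n_individuals = explicit[0].size
    variants, cols = [], []
    for vid, col in columns.items():
        meta = dict(pos=1_000_000, a1="A", a2="G", eaf=float("nan"))
        meta.update(variant_meta.get(vid, {}))
        variants.append(make_variant(vid, **meta))
        if col is None:
            col = rng.binomial(2, 0.3, size=n_individuals).astype(float)
        cols.append(np.asarray(col, dtype=float))
    return LdPanel(variants, np.column_stack(cols))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
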