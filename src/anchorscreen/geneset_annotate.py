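"""Gene-set annotation of consensus candidates.

Intersects the consensus pass set with a signaling gene set and a merged
puberty gene set to produce the final candidate table. Sets arrive as GMT
files (they come from versioned external databases, so they are inputs, not
something this package fetches). Symbols are matched case-insensitively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bulk_screen import ConsensusTable
from .io_formats import AnchorscreenError, GeneSet, normalize_symbol


def merge_sets(a: GeneSet, b: GeneSet, name: str) -> GeneSet:
    """Union of two gene sets under symbol normalization, with provenance in
    ``source`` (idempotent: merging a set with itself reproduces it)."""
    if not a.members or not b.members:
        raise AnchorscreenError("cannot merge an empty gene set")
    members = frozenset(a.members) | frozenset(b.members)
    if a.members == b.members:
        source = a.source or b.source
    else:
        source = f"union({a.name},{b.name})"
    return GeneSet(name=name, members=members, source=source)


def annotate(
    consensus: ConsensusTable,
    signaling: GeneSet,
    puberty: GeneSet,
    combine: str = "and",
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Flag consensus genes by gene-set membership and call final candidates.

    ``final`` requires the consensus pass flag plus membership in both sets
    (``combine='and'``, the default) or in either (``combine='or'``).
    ``exclude`` removes genes (typically the anchor itself) from the final
    call. Rows are ordered final-first by |mean r| descending, ties broken by
    symbol; an empty pass set yields an empty final set, not an error.
    """
    if combine not in ("and", "or"):
        raise AnchorscreenError(f"combine must be 'and' or 'or', got {combine!r}")
    table = consensus.table.copy()
    norm = table["gene"].map(normalize_symbol)
    table["in_signaling"] = norm.isin(signaling.members).to_numpy()
    table["in_puberty"] = norm.isin(puberty.members).to_numpy()
    if combine == "and":
        in_sets = table["in_signaling"] & table["in_puberty"]
    else:
        in_sets = table["in_signaling"] | table["in_puberty"]
    excluded = norm.isin({normalize_symbol(g) for g in exclude})
    table["final"] = table["pass"] & in_sets & ~excluded

    abs_mean_r = table["mean_r"].abs().fillna(-np.inf)
    order = np.lexsort((
        table["gene"].to_numpy(),
        -abs_mean_r.to_numpy(),
        ~table["final"].to_numpy(),
    ))
    return table.iloc[order].reset_index(drop=True)


def final_candidates(annotated: pd.DataFrame) -> pd.DataFrame:
    """The final candidate rows of an annotated consensus table."""
    return annotated[annotated["final"]].reset_index(drop=True)
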