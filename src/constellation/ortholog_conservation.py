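"""Cross-species conservation of constellation assignments.

Given constellation calls for two classified genomes and a one-to-one
ortholog map, tabulate per group (from the first species' perspective) how
many genes keep the same constellation in the partner species, move to a
different one, or lack an ortholog altogether.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["read_ortholog_table", "conservation_matrix"]


def read_ortholog_table(path: str | Path) -> list[tuple[str, str]]:
    """Read an idA<TAB>idB pair table, rejecting many-to-many rows.

    Any gene appearing in more than one row disqualifies all of its rows;
    the number of rejected rows is logged.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected idA<TAB>idB")
            pairs.append((parts[0], parts[1]))
    seen_a: dict[str, int] = {}
    seen_b: dict[str, int] = {}
    for a, b in pairs:
        seen_a[a] = seen_a.get(a, 0) + 1
        seen_b[b] = seen_b.get(b, 0) + 1
    kept = [(a, b) for a, b in pairs if seen_a[a] == 1 and seen_b[b] == 1]
    if len(kept) < len(pairs):
        log.info("rejected %d many-to-many ortholog rows", len(pairs) - len(kept))
    return kept


def _call_groups(calls) -> dict[str, str]:
    if isinstance(calls, Mapping):
        return dict(calls)
    return {c.gene_id: c.group for c in calls}


def conservation_matrix(
    calls_a,
    calls_b,
    orthologs: Iterable[tuple[str, str]],
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-group conservation tallies for species A genes.

    conserved: ortholog classified in the same group in species B;
    different: ortholog classified in another group; missing: no usable
    ortholog (absent from the map or unclassified in B, the latter logged).
    ``exclude`` removes genes (e.g. duplicates) from the tally entirely.
    Percentages are over the per-group gene counts.
    """
    groups_a = _call_groups(calls_a)
    groups_b = _call_groups(calls_b)
    exclude = set(exclude)
    partner = {}
    for a, b in orthologs:
        if a in partner:
            raise ValueError(f"gene {a} appears twice in the ortholog map")
        partner[a] = b

    counts: dict[str, dict[str, int]] = {}
    n_unclassified = 0
    for gene, group in groups_a.items():
        if gene in exclude or group == "CONFLICT":
            continue
        row = counts.setdefault(group, {"conserved": 0, "different": 0, "missing": 0})
        other = partner.get(gene)
        if other is None:
            row["missing"] += 1
        elif other not in groups_b or groups_b[other] == "CONFLICT":
            n_unclassified += 1
            row["missing"] += 1
        elif groups_b[other] == group:
            row["conserved"] += 1
        else:
            row["different"] += 1
    if n_unclassified:
        log.info("%d orthologs point to unclassified genes; counted as missing", n_unclassified)

    rows = []
    for group in sorted(counts):
        row = counts[group]
        size = sum(row.values())
        rows.append(
            {
                "group": group,
                "n": size,
                **row,
                "pct_conserved": 100.0 * row["conserved"] / size,
                "pct_different": 100.0 * row["different"] / size,
                "pct_missing": 100.0 * row["missing"] / size,
            }
        )
    return pd.DataFrame(rows).set_index("group")
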