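"""Recovery metrics comparing pipeline output against synthetic ground truth."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .hostlink import HostLink
from .pipeline import PipelineResult
from .synthio import TruthHostLink


def membership_recovery(truth: Mapping[str, str], recovered: Mapping[str, str]) -> float:
    """Fraction of contigs grouped into their true population.

    Each recovered cluster is credited with its best-overlapping truth
    population; the score is the summed overlap over all contigs (1.0 when
    the partitions coincide).
    """
    contigs = sorted(set(truth) & set(recovered))
    if not contigs:
        raise ValueError("no contigs shared between truth and recovered maps")
    by_cluster: dict[str, list[str]] = {}
    for c in contigs:
        by_cluster.setdefault(recovered[c], []).append(c)
    correct = 0
    for members in by_cluster.values():
        counts: dict[str, int] = {}
        for c in members:
            counts[truth[c]] = counts.get(truth[c], 0) + 1
        correct += max(counts.values())
    return correct / len(contigs)


def cluster_ari(truth: Mapping[str, str], recovered: Mapping[str, str]) -> float:
    """Adjusted Rand index between two labelings over their shared keys."""
    keys = sorted(set(truth) & set(recovered))
    if not keys:
        raise ValueError("no shared keys")
    return float(adjusted_rand_score([truth[k] for k in keys], [recovered[k] for k in keys]))


def hostlink_recovery(
    truth_links: Sequence[TruthHostLink],
    recovered_links: Sequence[HostLink],
    genome_votu: Mapping[str, str],
) -> tuple[float, int]:
    """(recall over planted (host, virus) pairs, count of spurious links).

    ``genome_votu`` maps the synthetic viral genome ids onto recovered vOTU
    ids so that truth records and pipeline links share a namespace.
    """
    planted = {(l.host, genome_votu[l.virus]) for l in truth_links}
    found = {(l.host, l.votu) for l in recovered_links}
    if not planted:
        raise ValueError("truth contains no host links")
    recall = len(planted & found) / len(planted)
    spurious = len(found - planted)
    return recall, spurious


def genome_votu_map(result: PipelineResult) -> dict[str, str]:
    """Map each synthetic viral genome id to its recovered vOTU id."""
    return {
        g: result.membership[f"{g}.c1"]
        for g in result.community.genomes
        if f"{g}.c1" in result.membership
    }


def recovery_report(result: PipelineResult) -> dict[str, float]:
    """All end-to-end recovery metrics for one pipeline run."""
    truth = result.truth
    non_contam = {
        c: v for c, v in truth.votu_memberships.items() if c not in truth.contaminants
    }
    gv = genome_votu_map(result)
    link_recall, spurious = hostlink_recovery(truth.host_links, result.host_links, gv)
    votu_hab: dict[str, set[str]] = {}
    for h, pool in result.community.habitat_pools.items():
        for g in pool:
            votu_hab.setdefault(g, set()).add(h)

    # habitat presence recovered from detection, compared to planted pools
    sharing = result.ecology["sharing"]
    recovered_pairwise = sharing.pairwise_shared
    habitats = list(result.config.community.habitats)
    planted_shared = pd.DataFrame(0, index=habitats, columns=habitats)
    for a in habitats:
        for b in habitats:
            planted_shared.loc[a, b] = len(
                {g for g in result.community.habitat_pools[a]}
                & {g for g in result.community.habitat_pools[b]}
            )
    # translate recovered vOTU ids back to genome ids for comparison
    votu_genome = {v: g for g, v in gv.items()}
    rec_shared = pd.DataFrame(0, index=habitats, columns=habitats)
    for a in habitats:
        for b in habitats:
            sa = {votu_genome.get(v) for v in sharing.per_habitat.get(a, set())}
            sb = {votu_genome.get(v) for v in sharing.per_habitat.get(b, set())}
            rec_shared.loc[a, b] = len((sa & sb) - {None})
    overlap_exact = bool((rec_shared.values == planted_shared.values).all())

    folds = result.ecology["folds"]
    configured = pd.Series(result.config.community.habitat_fold_gradient)
    fold_err = float((folds[configured.index] / configured - 1).abs().max())

    return {
        "votu_membership_recovery": membership_recovery(non_contam, result.membership),
        "vc_ari": cluster_ari(truth.vc_assignments, result.vc_assignment.membership),
        "hostlink_recall": link_recall,
        "hostlink_spurious": float(spurious),
        "contaminants_flagged": float(
            len(set(result.flagged) & truth.contaminants) / max(1, len(truth.contaminants))
        ),
        "habitat_overlap_exact": float(overlap_exact),
        "max_fold_error": fold_err,
        "multi_habitat_fraction": sharing.multi_habitat_fraction,
    }
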