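"""Independent brute-force reference implementations.

Each oracle is a deliberately naive, loop-based transcription of the rule it
checks, sharing no code with the package so that agreement is meaningful:

* median-genome module taxonomy (median of per-family genome counts, top-m
  genomes by family carriage, phylum tally);
* the breadth statistic (integer arithmetic for the inclusive >= 1/3 rule);
* single-linkage dereplication at an ANI threshold (BFS components plus the
  most-complete / least-contaminated / lexicographic representative rule).
"""

from __future__ import annotations

import math
from statistics import median


def oracle_module_taxonomy(family_ids, presence, phylum_of):
    """presence: dict family -> set of genomes; phylum_of: genome -> phylum.

    Returns (m, retained list, distribution dict).
    """
    genomes = sorted(phylum_of)
    counts = [len(presence[f] & set(genomes)) for f in family_ids]
    m = int(math.floor(float(median(counts)) + 0.5))
    carriage = {
        g: sum(1 for f in family_ids if g in presence[f]) for g in genomes
    }
    ranked = sorted(genomes, key=lambda g: (-carriage[g], g))
    retained = ranked[:m]
    dist: dict[str, int] = {}
    for g in retained:
        dist[phylum_of[g]] = dist.get(phylum_of[g], 0) + 1
    return m, retained, dist


def oracle_breadth(hit_rows, genome_phylum, threshold=0.001):
    """hit_rows: iterable of (family, genome, evalue); genome_phylum: genome -> phylum.

    Returns dict family -> (has_hit, n_phyla_passing, breadth_pct) where the
    1/3 phylum rule is evaluated in exact integer arithmetic
    (3 * hits >= genomes).  Families are those appearing in hit_rows.
    """
    phyla: dict[str, list[str]] = {}
    for g, ph in genome_phylum.items():
        phyla.setdefault(ph, []).append(g)
    n_phyla = len(phyla)
    fams = sorted({f for f, _, _ in hit_rows})
    out = {}
    for f in fams:
        hit_genomes = {g for ff, g, e in hit_rows if ff == f and e <= threshold}
        has_hit = len(hit_genomes & set(genome_phylum)) > 0
        n_pass = 0
        for ph, members in phyla.items():
            k = sum(1 for g in members if g in hit_genomes)
            if 3 * k >= len(members):
                n_pass += 1
        breadth = 100.0 * n_pass / n_phyla if has_hit else None
        out[f] = (has_hit, n_pass if has_hit else 0, breadth)
    return out


def oracle_dereplicate(ani, completeness, contamination, threshold=95.0):
    """ani: dict[(a, b)] -> percent (symmetric pairs may be given once).

    Returns (clusters as frozensets, representative per cluster) computed by
    BFS over the >=threshold graph.
    """
    genomes = sorted(completeness)

    def linked(a, b):
        v = ani.get((a, b), ani.get((b, a), 0.0))
        return v >= threshold

    seen: set[str] = set()
    clusters = []
    for g in genomes:
        if g in seen:
            continue
        comp = {g}
        queue = [g]
        while queue:
            cur = queue.pop()
            for other in genomes:
                if other not in comp and linked(cur, other):
                    comp.add(other)
                    queue.append(other)
        seen |= comp
        clusters.append(frozenset(comp))
    reps = {}
    for comp in clusters:
        reps[comp] = min(
            comp, key=lambda g: (-completeness[g], contamination[g], g)
        )
    return clusters, reps
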