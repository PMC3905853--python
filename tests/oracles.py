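"""Independent brute-force reference implementations used by the tests.

These deliberately share no code with the package: quadratic scans,
transitive closures and exact enumerations against which the real
implementations are checked.
"""

from fractions import Fraction
from math import comb

from drelink.annotation import DRE, INTRAGENIC


def brute_force_pair_counts(contacts_by_dataset, classified, genes, flank=1000):
    """Quadratic scan: every contact x every (DRE, intragenic-DHS) pair."""
    dres = [c for c in classified if c.category == DRE]
    idhs = [c for c in classified if c.category == INTRAGENIC]
    gene_ids = {g.gene_id for g in genes}
    counts = {}  # (dre_id, gene_id, dataset) -> {dhs_id: n}
    for dataset, contacts in contacts_by_dataset.items():
        for ct in contacts:
            ends = [(ct.chrom1, ct.pos1), (ct.chrom2, ct.pos2)]
            for e_dre, e_dhs in (ends, ends[::-1]):
                for d in dres:
                    if d.interval.chrom != e_dre[0]:
                        continue
                    if not (d.interval.start <= e_dre[1] < d.interval.end):
                        continue
                    for h in idhs:
                        if h.interval.chrom != e_dhs[0]:
                            continue
                        c = (h.interval.start + h.interval.end) // 2
                        if not (c - flank <= e_dhs[1] < c + flank):
                            continue
                        for gid in h.host_genes:
                            if gid not in gene_ids:
                                continue
                            key = (d.dhs_id, gid, dataset)
                            counts.setdefault(key, {})
                            counts[key][h.dhs_id] = counts[key].get(h.dhs_id, 0) + 1
    # max rule
    out = {}
    for (dre_id, gid, dataset), per_dhs in counts.items():
        out[(dre_id, gid, dataset)] = max(per_dhs.values())
    return out


def transitive_closure_clusters(intervals, gap):
    """Clusters = connected components of the pairwise gap <= gap relation."""
    ids = list(intervals)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in ids:
        for j in ids:
            a, b = intervals[i], intervals[j]
            if a.chrom != b.chrom:
                continue
            g = max(0, max(a.start, b.start) - min(a.end, b.end))
            if g <= gap:
                parent[find(i)] = find(j)
    comps = {}
    for i in ids:
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(v) for v in comps.values()}


def brute_force_predictions(counts_by_cell_line, pcc, pcc_cutoff, read_cutoff):
    """Literal per-pair rule evaluation; returns {pair_key: evidence_route}."""
    out = {}
    for cell, table in counts_by_cell_line.items():
        for key, reps in table.items():
            r = pcc.get(key)
            if r is None or not (r > pcc_cutoff):
                continue
            count_rule = any(n > read_cutoff for n in reps)
            rescue = len(reps) >= 2 and all(n >= 1 for n in reps)
            if not (count_rule or rescue):
                continue
            route = "count_rule" if count_rule else "rescue_rule"
            if key in out and out[key] == "count_rule":
                continue
            if key in out and route == "count_rule":
                out[key] = "count_rule"
            elif key not in out:
                out[key] = route
    return out


def fisher_exact_two_sided(a, b, c, d):
    """Exact two-sided Fisher p by full hypergeometric enumeration, in
    rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    num_a = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        nk = comb(r1, k) * comb(r2, c1 - k)
        if nk <= num_a:
            total += nk
    return float(Fraction(total, comb(n, c1)))
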