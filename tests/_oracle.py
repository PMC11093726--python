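"""Brute-force structural classifier used as an independent oracle.

Everything here is computed with naive loops over the raw reference
transcript list — no interval index, no catalogs — so it stays independent
of the production classifier's data structures.
"""

from __future__ import annotations

from isocurate.models import TranscriptModel


def _gene_groups(reference, min_ref_len):
    txs = [t for t in reference if t.spliced_length >= min_ref_len]
    genes = {}
    for t in txs:
        genes.setdefault(t.gene_id, []).append(t)
    spans = {g: (v[0].chrom, v[0].strand,
                 min(t.start for t in v), max(t.end for t in v))
             for g, v in genes.items()}
    return txs, genes, spans


def _junctions(tx):
    return [(a.end, b.start) for a, b in zip(tx.exons, tx.exons[1:])]


def _ends_diff(q, r):
    if q.strand == "+":
        return q.tss - r.tss, q.tts - r.tts
    return r.tss - q.tss, r.tts - q.tts


def _closeness(q, r):
    d5, d3 = _ends_diff(q, r)
    return abs(d5) + abs(d3)


def oracle_classify(query: TranscriptModel, reference, min_ref_len=200,
                    window=50):
    """Returns (category, subcategory) by exhaustive enumeration."""
    txs, genes, spans = _gene_groups(reference, min_ref_len)
    same_locus_genes = sorted(
        g for g, (c, s, lo, hi) in spans.items()
        if c == query.chrom and s == query.strand
        and lo < query.end and query.start < hi)
    opposite = any(c == query.chrom and s != query.strand
                   and lo < query.end and query.start < hi
                   for c, s, lo, hi in spans.values())

    if len(query.exons) == 1:
        return _oracle_mono(query, genes, same_locus_genes, opposite)

    qj = _junctions(query)
    candidates = [t for g in same_locus_genes for t in genes[g]
                  if len(t.exons) > 1]

    full = [t for t in candidates if _junctions(t) == qj]
    if full:
        ref = sorted(full, key=lambda t: (_closeness(query, t),
                                          t.transcript_id))[0]
        d5, d3 = _ends_diff(query, ref)
        if abs(d5) > window and abs(d3) > window:
            return "FSM", "alternative_3end5end"
        if abs(d5) > window:
            return "FSM", "alternative_5end"
        if abs(d3) > window:
            return "FSM", "alternative_3end"
        return "FSM", "reference_match"

    isms = []
    for t in candidates:
        rj = _junctions(t)
        for i in range(len(rj) - len(qj) + 1):
            if rj[i:i + len(qj)] == qj and len(qj) < len(rj):
                isms.append((t, i))
                break
    if isms:
        ref, off = sorted(isms, key=lambda p: (_closeness(query, p[0]),
                                               p[0].transcript_id))[0]
        rj = _junctions(ref)
        for exon in query.exons:
            for (js, je) in rj:
                if (js, je) not in qj and exon.start < js and je < exon.end:
                    return "ISM", "intron_retention"
        left, right = off > 0, off + len(qj) < len(rj)
        if query.strand == "-":
            left, right = right, left
        if left and right:
            return "ISM", "internal_fragment"
        if left:
            return "ISM", "3prime_fragment"
        return "ISM", "5prime_fragment"

    # genes with exonic overlap on the same strand
    exonic = []
    for g in same_locus_genes:
        found = False
        for t in genes[g]:
            for re_ in t.exons:
                for qe in query.exons:
                    if qe.start < re_.end and re_.start < qe.end:
                        found = True
        if found:
            exonic.append(g)

    if len(exonic) >= 2:
        for i, g1 in enumerate(exonic):
            for g2 in exonic[i + 1:]:
                _, _, lo1, hi1 = spans[g1]
                _, _, lo2, hi2 = spans[g2]
                if hi1 <= lo2 or hi2 <= lo1:
                    return "fusion", "multi-exon"

    if exonic:
        donors, acceptors, known = set(), set(), set()
        for g in exonic:
            for t in genes[g]:
                for (js, je) in _junctions(t):
                    known.add((js, je))
                    if t.strand == "+":
                        donors.add(js)
                        acceptors.add(je)
                    else:
                        donors.add(je)
                        acceptors.add(js)
        novel_site = False
        for (js, je) in qj:
            d, a = (js, je) if query.strand == "+" else (je, js)
            if d not in donors or a not in acceptors:
                novel_site = True
        if novel_site:
            return "NNC", "at_least_one_novel_splicesite"
        if all(j in known for j in qj):
            return "NIC", "combination_of_known_junctions"
        return "NIC", "combination_of_known_splicesites"

    if same_locus_genes:
        return "genic_genomic", "multi-exon"
    if opposite:
        return "antisense", "multi-exon"
    return "intergenic", "multi-exon"


def _oracle_mono(query, genes, same_locus_genes, opposite):
    exon = query.exons[0]
    candidates = [t for g in same_locus_genes for t in genes[g]]
    monos = [t for t in candidates if len(t.exons) == 1
             and t.start < query.end and query.start < t.end]
    if monos:
        return "FSM", "mono-exon"
    for t in candidates:
        if len(t.exons) > 1:
            for e in t.exons:
                if e.start <= exon.start and exon.end <= e.end:
                    return "ISM", "mono-exon"
    for t in candidates:
        for (js, je) in _junctions(t):
            if exon.start < js and je < exon.end:
                return "NIC", "mono-exon_by_intron_retention"
    for t in candidates:
        for e in t.exons:
            if exon.start < e.end and e.start < exon.end:
                return "NIC", "mono-exon"
    if same_locus_genes:
        return "genic_genomic", "mono-exon"
    if opposite:
        return "antisense", "mono-exon"
    return "intergenic", "mono-exon"
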