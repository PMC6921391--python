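"""Independent brute-force reference implementations used only by tests.

Everything here evaluates the model definitions directly — raw products,
explicit loops, no log-space tricks, no shared code with the package — so
the package's vectorized log-space implementations can be checked against
first principles on tiny instances.
"""

import itertools

import numpy as np

PRESENT, ABSENT, MISSING = "P", "A", "NA"


def brute_cell_likelihood(p_alt, alt, ref):
    """P(C_i|S_n) as the literal product over SNVs of p^N_A (1-p)^N_R."""
    n_snvs, n_cells = alt.shape
    k = p_alt.shape[1]
    lik = np.ones((n_cells, k))
    for i in range(n_cells):
        for n in range(k):
            for v in range(n_snvs):
                lik[i, n] *= p_alt[v, n] ** alt[v, i]
                lik[i, n] *= (1.0 - p_alt[v, n]) ** ref[v, i]
    return lik


def brute_posterior(p_alt, alt, ref):
    """Equal-prior Bayes posterior from the raw likelihood products."""
    lik = brute_cell_likelihood(p_alt, alt, ref)
    return lik / lik.sum(axis=1, keepdims=True)


def brute_m_step(alt, ref, posterior, pseudo_alt, pseudo_total):
    n_snvs, n_cells = alt.shape
    k = posterior.shape[1]
    p = np.empty((n_snvs, k))
    for n in range(k):
        for v in range(n_snvs):
            num = pseudo_alt
            den = pseudo_total
            for i in range(n_cells):
                num += alt[v, i] * posterior[i, n]
                den += (alt[v, i] + ref[v, i]) * posterior[i, n]
            p[v, n] = num / den
    w = posterior.sum(axis=0)
    return p, w / w.sum()


def brute_log_likelihood(p_alt, weights, alt, ref):
    lik = brute_cell_likelihood(p_alt, alt, ref)
    return float(np.sum(np.log((lik * weights[None, :]).sum(axis=1))))


def brute_het_log10_gp(a, r, error):
    """Normalized log10 P(RA) from pooled counts, plain-float arithmetic."""
    probs = [error, 0.5, 1.0 - error]
    lik = [p**a * (1 - p) ** r for p in probs]
    total = sum(lik)
    return np.log10(lik[1] / total)


def pa_token(alt_count, ref_count, min_count=10):
    """Presence/absence call from pooled cluster counts, by the rule book."""
    if alt_count > min_count:
        return PRESENT
    if ref_count > min_count and alt_count == 0:
        return ABSENT
    return MISSING


def _separates(mat):
    cols = [tuple(mat[:, j]) for j in range(mat.shape[1])]
    return len(set(cols)) == len(cols)


def minimal_separating_size(pa_array):
    """Exhaustive minimum cardinality of a row subset separating all columns.

    ``pa_array`` is a token matrix; only NA-free rows are eligible.
    Returns None when no subset separates.
    """
    eligible = [
        i for i in range(pa_array.shape[0])
        if MISSING not in pa_array[i].tolist()
    ]
    full = pa_array[eligible]
    if not eligible or not _separates(full):
        return None
    for size in range(1, len(eligible) + 1):
        for combo in itertools.combinations(range(len(eligible)), size):
            if _separates(full[list(combo)]):
                return size
    return None


def sibling_concordance_probability(f):
    """P(two full siblings share a genotype) at a biallelic SNP, by full
    enumeration over parental genotypes and Mendelian transmissions."""
    geno_probs = {0: (1 - f) ** 2, 1: 2 * f * (1 - f), 2: f**2}
    # transmission distribution of one allele from a parent genotype
    transmit = {0: {0: 1.0}, 1: {0: 0.5, 1: 0.5}, 2: {1: 1.0}}
    p_same = 0.0
    for g1, p1 in geno_probs.items():
        for g2, p2 in geno_probs.items():
            dist = {}
            for a1, pa1 in transmit[g1].items():
                for a2, pa2 in transmit[g2].items():
                    dist[a1 + a2] = dist.get(a1 + a2, 0.0) + pa1 * pa2
            p_same += p1 * p2 * sum(p**2 for p in dist.values())
    return p_same


def unrelated_concordance_probability(f):
    geno_probs = [(1 - f) ** 2, 2 * f * (1 - f), f**2]
    return sum(p**2 for p in geno_probs)
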