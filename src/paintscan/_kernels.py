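"""Numba kernels for the inner loop of the Wright-Fisher simulator.

The population's haplotypes are stored as flat, concatenated tract arrays
(`ends`, `anc`) indexed by per-haplotype `offsets`.  All randomness
(crossover counts/positions, parent choices, starting haplotypes) is drawn
with numpy *before* calling into the kernel, so the kernel itself is
deterministic and the simulation is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gamete_kernel(
    p_ends,  # float64[:] parent tract end positions, flat
    p_anc,  # int8[:]    parent tract ancestries, flat
    p_off,  # int64[:]   per-haplotype offsets into the flat arrays
    p_alleles,  # int8[:, :] (n_parent_haplotypes, n_sites) allele states
    parent,  # int64[:]   diploid parent index per gamete
    start,  # int8[:]    starting haplotype (0/1) per gamete
    xo,  # float64[:] crossover positions, flat, sorted within gametes
    xo_off,  # int64[:]   per-gamete offsets into `xo`
    site_pos,  # float64[:] selected-site positions on this chromosome
    length,  # float64    chromosome length
    out_ends,  # float64[:] output tract ends (bound-sized scratch)
    out_anc,  # int8[:]    output tract ancestries
    bound_off,  # int64[:]  per-gamete scratch offsets (upper bounds)
    out_n,  # int64[:]   actual tract count written per gamete
    out_alleles,  # int8[:, :] (n_gametes, n_sites) child allele states
    out_site_anc,  # int8[:, :] (n_gametes, n_sites) child ancestry at each site
):
    """Produce one recombinant gamete per entry of `parent`.

    Each gamete alternates between the two parental haplotypes at the given
    crossover positions, starting from `start`.  Adjacent output tracts with
    equal ancestry are merged, so the child tract list is normalized.
    Crossovers at or outside (0, length) and exact duplicates are ignored
    (a crossover at a chromosome end has no effect; duplicates are removed).
    """
    n_gam = parent.shape[0]
    n_sites = site_pos.shape[0]
    for j in range(n_gam):
        # insertion-sort this gamete's crossovers in place (counts are tiny)
        lo_x = xo_off[j]
        hi_x = xo_off[j + 1]
        for a_i in range(lo_x + 1, hi_x):
            v = xo[a_i]
            b_i = a_i - 1
            while b_i >= lo_x and xo[b_i] > v:
                xo[b_i + 1] = xo[b_i]
                b_i -= 1
            xo[b_i + 1] = v
        h0 = 2 * parent[j]
        side = start[j]
        i0 = 0
        i1 = 0
        o = bound_off[j]
        m = 0
        seg_start = 0.0
        a_prev = np.int8(-1)
        kb = xo_off[j]
        k_end = xo_off[j + 1]
        prev_b = -1.0
        while True:
            if kb < k_end:
                b = xo[kb]
                if b <= 0.0 or b >= length or b == prev_b:
                    prev_b = b
                    kb += 1
                    continue
                prev_b = b
            else:
                b = length
            seg_end = b
            hap = h0 + side
            base = p_off[hap]
            i = i0 if side == 0 else i1
            # advance to the tract containing seg_start
            while p_ends[base + i] <= seg_start:
                i += 1
            # copy the current haplotype's tracts over [seg_start, seg_end)
            while True:
                te = p_ends[base + i]
                a = p_anc[base + i]
                e = te if te < seg_end else seg_end
                if m > 0 and a == a_prev:
                    out_ends[o + m - 1] = e
                else:
                    out_ends[o + m] = e
                    out_anc[o + m] = a
                    a_prev = a
                    m += 1
                if te >= seg_end:
                    break
                i += 1
            # the donating haplotype supplies the allele at sites it covers
            for s in range(n_sites):
                q = site_pos[s]
                if seg_start <= q < seg_end:
                    out_alleles[j, s] = p_alleles[hap, s]
            if side == 0:
                i0 = i
            else:
                i1 = i
            if kb >= k_end:
                break
            kb += 1
            seg_start = seg_end
            side = 1 - side
        out_n[j] = m
        # child ancestry at each selected site, via binary search in the
        # freshly built (normalized) child tract list
        for s in range(n_sites):
            q = site_pos[s]
            lo = 0
            hi = m - 1
            while lo < hi:
                mid = (lo + hi) // 2
                if out_ends[o + mid] > q:
                    hi = mid
                else:
                    lo = mid + 1
            out_site_anc[j, s] = out_anc[o + lo]


@njit(cache=True)
def compact_kernel(out_ends, out_anc, bound_off, out_n, new_off, new_ends, new_anc):
    """Pack bound-sized scratch tract arrays into exact-size flat arrays."""
    n_gam = out_n.shape[0]
    for j in range(n_gam):
        src = bound_off[j]
        dst = new_off[j]
        for t in range(out_n[j]):
            new_ends[dst + t] = out_ends[src + t]
            new_anc[dst + t] = out_anc[src + t]
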