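import numpy as np
import pytest

import synphen as sp


@pytest.fixture(scope="session")
def identical_pair():
    """Reference and derived genomes that are byte-identical (no mutations)."""
    return sp.simulate_genome_pair(10_000, 5, 0.0, 0.0, 0, 0, 1, seed=1)


@pytest.fixture(scope="session")
def rearranged_pair():
    """Substitutions + one large inversion + one translocation, fragmented."""
    return sp.simulate_genome_pair(
        60_000, 12, 0.01, 0.0, n_inversions=1, n_translocations=1,
        n_scaffolds=2, seed=5, rearrangement_len=(11_000, 15_000),
    )


@pytest.fixture(scope="session")
def noiseless_screen():
    truth = sp.default_plate_truth(n_compounds=24, noise_sd=0.0, seed=11)
    meas = sp.simulate_plate_screen(truth, growth_amplitude=0.6, seed=11)
    return truth, meas


def synteny_map(pair, k=20):
    anchors = sp.find_anchors({"reference": pair.reference}, pair.derived_scaffolds, k=k)
    chains = sp.filter_chains(sp.build_chains(anchors))
    return sp.build_coordinate_map(chains), chains


def true_blocks(pair):
    """Maximal collinear blocks implied by the truth coordinate map, as
    [ref_start, ref_end, scaffold, qry_first, qry_last, strand] rows."""
    cmap = pair.coordinate_map
    blocks = []
    cur = None
    for p in range(len(pair.reference)):
        img = cmap[p]
        if img == "deleted":
            cur = None
            continue
        scaf, pos, strand = img
        step = 1 if strand == "+" else -1
        if cur and cur[2] == scaf and cur[5] == strand and pos == cur[4] + step:
            cur[1] = p + 1
            cur[4] = pos
        else:
            cur = [p, p + 1, scaf, pos, pos, strand]
            blocks.append(cur)
    return blocks


def blocks_bridgeable(blocks, max_gap):
    """True when some pair of collinear blocks could legitimately chain across
    a gap <= max_gap on both sequences (e.g. a translocation displaced by
    less than the gap allowance); the chain-count recovery invariant only
    applies when this is False."""
    for i, a in enumerate(blocks):
        for b in blocks[i + 1:]:
            if a[2] != b[2] or a[5] != b[5] or b[0] - a[1] > max_gap:
                continue
            if a[5] == "+":
                fwd = min(b[3], b[4]) > min(a[3], a[4])
                qry_gap = min(b[3], b[4]) - max(a[3], a[4]) - 1
            else:
                fwd = max(b[3], b[4]) < max(a[3], a[4])
                qry_gap = min(a[3], a[4]) - max(b[3], b[4]) - 1
            if fwd and qry_gap <= max_gap:
                return True
    return False
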