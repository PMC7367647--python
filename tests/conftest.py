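import numpy as np
import pytest

import plasmacin as pc


@pytest.fixture(scope="session")
def toy_build():
    return pc.GenomeBuild.from_dict("toy", {"c1": 1_000_000})


@pytest.fixture(scope="session")
def toy_grid(toy_build):
    return pc.make_bin_grid(toy_build, 200_000)


@pytest.fixture(scope="session")
def mini_grid():
    """Small two-chromosome frame (600 bins of 200 kb) for simulations."""
    build = pc.GenomeBuild.from_dict(
        "mini", {"c1": 60_000_000, "c2": 60_000_000})
    return pc.make_bin_grid(build, 200_000)


@pytest.fixture(scope="session")
def mini_panel(mini_grid):
    """Ten disjoint 20-bin pseudo-segments on the mini frame."""
    segs = []
    for k in range(10):
        chrom = "c1" if k < 5 else "c2"
        off = (k % 5) * 12_000_000
        segs.append(pc.PanelSegment(
            name=f"s{k}+", direction="gain",
            interval=pc.GenomicInterval(chrom, off, off + 4_000_000)))
    return segs


@pytest.fixture(scope="session")
def liver_panel():
    return pc.load_panel()


@pytest.fixture(scope="session")
def hg19_grid():
    return pc.make_bin_grid(pc.GenomeBuild.hg19())


# ---- independent oracles -------------------------------------------------

def brute_force_max_arc(x, min_width=2):
    """Exhaustive O(n^2) search over all admissible arcs, prefix-sum based;
    ties broken toward smallest (i, j) with the same near-tie tolerance as
    the implementation (complementary arcs are float-path twins)."""
    x = np.asarray(x, float)
    n = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    Q = np.concatenate(([0.0], np.cumsum(x * x)))
    best = None
    ss_floor = 1e-10 * max(float(Q[n]), 1e-30)  # same zero-SS convention
    for i in range(n):
        for j in range(i + min_width, min(n, i + n - min_width) + 1):
            m, k = j - i, n - (j - i)
            s_in = S[j] - S[i]
            mean_in, mean_out = s_in / m, (S[n] - s_in) / k
            ss = max(0.0, (Q[j] - Q[i] - s_in**2 / m)
                     + (Q[n] - Q[j] + Q[i] - (S[n] - s_in)**2 / k))
            d = abs(mean_in - mean_out)
            if ss <= ss_floor:
                t = 0.0 if d <= 1e-12 * max(1.0, d) else float("inf")
            else:
                t = d / np.sqrt(ss / (n - 2) * (1 / m + 1 / k))
            if best is None or t > best[2] + 1e-9 * max(1.0, best[2]):
                best = (i, j, t)
    return best


def pairwise_concordance_auc(labels, stats):
    """U-statistic AUC: P(case stat > control stat) + 0.5 P(tie)."""
    cases = [s for l, s in zip(labels, stats) if l == "cancer"]
    controls = [s for l, s in zip(labels, stats) if l == "control"]
    wins = ties = 0
    for c in cases:
        for h in controls:
            if c > h:
                wins += 1
            elif c == h:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def enumerate_fisher_p(table):
    """Two-sided Fisher p by explicit enumeration of the hypergeometric
    support (point probabilities <= observed, with a relative tolerance)."""
    from math import comb

    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {x: comb(r1, x) * comb(n - r1, c1 - x) / denom
             for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


@pytest.fixture(scope="session")
def oracles():
    return {
        "max_arc": brute_force_max_arc,
        "auc": pairwise_concordance_auc,
        "fisher_p": enumerate_fisher_p,
    }
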