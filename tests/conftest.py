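import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dyadcoord.simulate import SimConfig
from dyadcoord.trace import MovementTrace, TrialPair

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240621)


def make_sinusoid(freq=1.4, fs=50.0, duration=90.0, amp=1.0, phase=0.0, actor="participant"):
    t = np.arange(int(round(duration * fs))) / fs
    return MovementTrace(t=t, x=amp * np.sin(2 * np.pi * freq * t + phase),
                         fs=fs, actor=actor)


@pytest.fixture
def sinusoid():
    return make_sinusoid


@pytest.fixture
def sinusoid_pair():
    def _make(freq=1.4, fs=50.0, duration=90.0, phase_offset=0.0, **kw):
        p = make_sinusoid(freq, fs, duration, phase=phase_offset, actor="participant")
        a = make_sinusoid(freq, fs, duration, actor="avatar")
        return TrialPair(participant=p, avatar=a, **kw)
    return _make


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A 6-participant synthetic study directory, generated once per run."""
    from dyadcoord.simulate import generate_study

    root = tmp_path_factory.mktemp("study")
    cfg = SimConfig(n_participants=6, seed=11)
    covariates, truth = generate_study(cfg, root)
    return root, cfg, covariates, truth


# ---------------------------------------------------------------------------
# naive brute-force reference implementations (independent oracles)


def brute_ami(x, max_lag):
    """AMI curve computed with explicit per-bin loops (same binning rule)."""
    import math

    x = list(map(float, x))
    n = len(x)
    out = []
    for tau in range(max_lag + 1):
        a = x[: n - tau]
        b = x[tau:]
        bins = min(64, math.ceil(math.sqrt(n - tau)))
        lo_a, hi_a = min(a), max(a)
        lo_b, hi_b = min(b), max(b)
        wa = (hi_a - lo_a) / bins or 1.0
        wb = (hi_b - lo_b) / bins or 1.0
        joint = {}
        for ai, bi in zip(a, b):
            ia = min(bins - 1, int((ai - lo_a) / wa))
            ib = min(bins - 1, int((bi - lo_b) / wb))
            joint[(ia, ib)] = joint.get((ia, ib), 0) + 1
        total = len(a)
        pa, pb = {}, {}
        for (ia, ib), c in joint.items():
            pa[ia] = pa.get(ia, 0) + c
            pb[ib] = pb.get(ib, 0) + c
        mi = 0.0
        for (ia, ib), c in joint.items():
            p = c / total
            mi += p * math.log2(p / ((pa[ia] / total) * (pb[ib] / total)))
        out.append(mi)
    return np.array(out)


def brute_embed(x, dim, delay):
    n = len(x) - (dim - 1) * delay
    return [[float(x[i + j * delay]) for j in range(dim)] for i in range(n)]


def brute_fnn(x, delay, max_dim, rtol=15.0, atol=2.0):
    """Kennel FNN fractions via exhaustive O(n^2) neighbour search."""
    import math

    x = list(map(float, x))
    sd = float(np.std(x))
    fractions = []
    for d in range(1, max_dim + 1):
        m = len(x) - d * delay
        pts = brute_embed(x, d, delay)[:m]
        n_false = 0
        for i in range(m):
            best_j, best_dist = -1, math.inf
            for j in range(m):
                if j == i:
                    continue
                dist = math.sqrt(sum((pts[i][k] - pts[j][k]) ** 2 for k in range(d)))
                if dist < best_dist or (dist == best_dist and j < best_j):
                    best_j, best_dist = j, dist
            extra = abs(x[i + d * delay] - x[best_j + d * delay])
            ratio = (extra / best_dist) if best_dist > 0 else (
                math.inf if extra > 0 else 0.0)
            r_d1 = math.sqrt(best_dist**2 + extra**2)
            if ratio > rtol or r_d1 > atol * sd:
                n_false += 1
        fractions.append(n_false / m)
    return np.array(fractions)


def brute_recurrence(ex_pts, ey_pts, radius):
    """Dense cross-recurrence matrix by explicit pairwise loops."""
    import math

    R = []
    for p in ex_pts:
        row = []
        for q in ey_pts:
            dist = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
            row.append(dist <= radius)
        R.append(row)
    return np.array(R, dtype=bool)


def brute_rec_pct(R):
    n = sum(1 for row in R for v in row if v)
    return 100.0 * n / (len(R) * len(R[0]))


def brute_maxline(R, min_line=2):
    """Longest diagonal run, found by walking every diagonal cell by cell."""
    n_x, n_y = len(R), len(R[0])
    best = 0
    for start_i in range(n_x):
        for start_j in range(n_y):
            if start_i > 0 and start_j > 0:
                continue  # only true diagonal starts
            i, j, run = start_i, start_j, 0
            while i < n_x and j < n_y:
                run = run + 1 if R[i][j] else 0
                best = max(best, run)
                i += 1
                j += 1
    return best if best >= min_line else 0
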