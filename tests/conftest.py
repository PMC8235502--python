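import numpy as np
import pytest

from stilquant.raster import BinaryMask, Calibration
from stilquant.synthetic import SlideSpec, render_slide

# small, fast slide used by most image-level tests: 2×2 mm at 4 µm/px
SMALL_SPEC = SlideSpec(
    microns_per_pixel=4.0,
    width_px=500,
    height_px=500,
    n_tumor_blobs=2,
    tumor_blob_radius_um=(300.0, 450.0),
    n_dcis=1,
    dcis_offset_um=(300.0, 450.0),
    seed=11,
)


@pytest.fixture(scope="session")
def small_render():
    return render_slide(SMALL_SPEC)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_mask(raster, mpp=2.0):
    raster = np.asarray(raster, dtype=bool)
    cal = Calibration(mpp, raster.shape[1], raster.shape[0])
    return BinaryMask(raster, cal)


# ---------------------------------------------------------------------------
# brute-force oracles (shared by unit and acceptance tests; deliberately
# naive double loops, independent of the FFT/EDT implementations)
# ---------------------------------------------------------------------------


def oracle_disk_fraction(raster: np.ndarray, radius_px: float) -> np.ndarray:
    h, w = raster.shape
    r = int(np.floor(radius_px + 1e-9))
    out = np.zeros((h, w))
    offsets = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dx * dx + dy * dy <= radius_px * radius_px + 1e-9
    ]
    for y in range(h):
        for x in range(w):
            num = den = 0
            for dy, dx in offsets:
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    den += 1
                    num += raster[yy, xx]
            out[y, x] = num / den
    return out


def oracle_dilate(raster: np.ndarray, radius_px: float) -> np.ndarray:
    """Pixel is set iff some true pixel center lies within radius."""
    h, w = raster.shape
    true_pts = np.argwhere(raster)
    out = np.zeros((h, w), dtype=bool)
    r2 = radius_px * radius_px + 1e-9
    for y in range(h):
        for x in range(w):
            d2 = ((true_pts[:, 0] - y) ** 2 + (true_pts[:, 1] - x) ** 2) if len(true_pts) else []
            out[y, x] = len(true_pts) > 0 and (np.asarray(d2) <= r2).any()
    return out


def oracle_erode(raster: np.ndarray, radius_px: float, border_is_foreground: bool) -> np.ndarray:
    """Pixel survives iff no false pixel (incl. outside unless ignored) is
    within radius."""
    h, w = raster.shape
    r = int(np.floor(radius_px + 1e-9))
    r2 = radius_px * radius_px + 1e-9
    out = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            if not raster[y, x]:
                continue
            ok = True
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if dx * dx + dy * dy > r2:
                        continue
                    yy, xx = y + dy, x + dx
                    inside = 0 <= yy < h and 0 <= xx < w
                    if inside and not raster[yy, xx]:
                        ok = False
                    if not inside and not border_is_foreground:
                        ok = False
                if not ok:
                    break
            out[y, x] = ok
    return out


def oracle_close_open(raster: np.ndarray, radius_px: float) -> np.ndarray:
    closed = oracle_erode(oracle_dilate(raster, radius_px), radius_px, border_is_foreground=True)
    return oracle_dilate(oracle_erode(closed, radius_px, border_is_foreground=False), radius_px)


def oracle_km(times, events):
    """Product-limit estimate by explicit risk-set bookkeeping.
    Returns (event_times, survival) at distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(times[events == 1]):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def oracle_logrank_z(times, events, group1):
    """O(events) summation of the two-sample log-rank statistic."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g = np.asarray(group1, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at = times >= t
        n, n1 = at.sum(), (at & g).sum()
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e / np.sqrt(var) if var > 0 else 0.0


def oracle_efron_loglik(beta, times, events, x):
    """Efron-ties Cox partial log-likelihood for one covariate."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        d = int(tied.sum())
        risk = times >= t
        sum_risk = np.sum(np.exp(beta * x[risk]))
        sum_tied = np.sum(np.exp(beta * x[tied]))
        ll += beta * x[tied].sum()
        for j in range(d):
            ll -= np.log(sum_risk - j / d * sum_tied)
    return ll


def oracle_spearman(a, b):
    """Rank correlation with average ranks for ties, via Pearson on ranks."""
    def avg_rank(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return ranks

    ra, rb = avg_rank(a), avg_rank(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))
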