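"""Control ensembles: CCA between CBGT activity features and DDM parameters.

Per network, the activity is summarized by 18 features: for each of the 8
lateralized populations (Cx, dSPN, iSPN, GPeP, GPeA, STN, GPi, Th) the sum
and the difference (left minus right) of the trial-averaged rates, plus
the single trial-averaged rates of the shared CxI and FSI.  Canonical
correlation analysis against the per-network DDM parameters (a, v, t, z)
yields three component pairs, labelled by their loading patterns:

* choice        — dominated by difference features and the drift rate v;
* responsiveness — boundary height a and onset time t load with the same
  sign (overall response speed);
* pliancy       — a and t load with opposite signs.

Bin-to-bin changes of the feature vector are projected onto the activity
loadings to give per-trial drive time series, and zone-to-zone feature
changes are projected through both loading sets to predict DDM-parameter
changes per zone transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, svd

from .claw import DtTertiles, StateSequence, ZonePartition
from .populations import POP_INDEX

LATERALIZED_FEATURES = ("Cx", "dSPN", "iSPN", "GPeP", "GPeA", "STN", "GPi", "Th")

#: Fixed order of the 18 feature columns.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{base}_{kind}" for base in LATERALIZED_FEATURES for kind in ("sum", "diff")
) + ("CxI", "FSI")

DDM_COLUMNS = ("a", "v", "t", "z")

ENSEMBLE_LABELS = ("choice", "responsiveness", "pliancy")


def trial_feature_vector(rates: np.ndarray) -> np.ndarray:
    """18-feature vector from an (18 populations x bins) rate block,
    averaging over bins."""
    mean = rates.mean(axis=1)
    return feature_vector_from_means(mean)


def feature_vector_from_means(mean: np.ndarray) -> np.ndarray:
    """18-feature vector from per-population mean rates."""
    out = np.empty(len(FEATURE_NAMES))
    j = 0
    for base in LATERALIZED_FEATURES:
        l, r = mean[POP_INDEX[base + "-L"]], mean[POP_INDEX[base + "-R"]]
        out[j] = l + r
        out[j + 1] = l - r
        j += 2
    out[j] = mean[POP_INDEX["CxI"]]
    out[j + 1] = mean[POP_INDEX["FSI"]]
    return out


def build_feature_matrix(trace_set) -> np.ndarray:
    """F_all: one row of 18 features per network (trial-averaged rates up
    to each trial's decision time, averaged over non-timeout trials)."""
    rows = []
    for _, trials in trace_set:
        ok = [t for t in trials if not t.timed_out]
        if not ok:
            raise ValueError("network with no completed trials")
        feats = np.array([trial_feature_vector(t.decision_rates()) for t in ok])
        rows.append(feats.mean(axis=0))
    return np.array(rows)


# --------------------------------------------------------------------- #
# CCA
# --------------------------------------------------------------------- #

@dataclass
class EnsembleModel:
    """Paired CCA loadings between activity features and DDM parameters.

    U (18 x k) and V (4 x k) are loadings in standardized units; columns
    are ordered by decreasing canonical correlation.  labels maps each
    ensemble name to its column index once `label_components` has run.
    """

    U: np.ndarray
    V: np.ndarray
    correlations: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    ddm_means: np.ndarray
    ddm_sds: np.ndarray
    labels: dict = field(default_factory=dict)
    label_confident: bool = True

    def column(self, label: str) -> int:
        return self.labels[label]

    def standardize_features(self, F: np.ndarray) -> np.ndarray:
        return (F - self.feature_means) / self.feature_sds

    def scale_features(self, dF: np.ndarray) -> np.ndarray:
        """Scale feature *changes* to standardized units (no centering)."""
        return dF / self.feature_sds


def _inv_sqrt(S: np.ndarray, ridge: float) -> np.ndarray:
    vals, vecs = eigh(S + ridge * np.eye(len(S)))
    vals = np.maximum(vals, ridge)
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def fit_cca(F: np.ndarray, D: np.ndarray, k: int = 3, ridge: float = 1e-8) -> EnsembleModel:
    """Canonical correlation analysis via whitened cross-covariance SVD.

    Columns of F and D are standardized internally; loadings are returned
    in standardized units with the sign convention that each activity-side
    column's largest-magnitude entry is positive.
    """
    F = np.asarray(F, dtype=float)
    D = np.asarray(D, dtype=float)
    n = F.shape[0]
    if D.shape[0] != n:
        raise ValueError("row mismatch between feature and DDM matrices")
    if n <= F.shape[1] + D.shape[1]:
        warnings.warn(
            f"only {n} networks for {F.shape[1]}+{D.shape[1]} variables; "
            "CCA will be regularized and may be unstable"
        )
    fm, fs = F.mean(axis=0), F.std(axis=0, ddof=1)
    dm, ds = D.mean(axis=0), D.std(axis=0, ddof=1)
    fs = np.where(fs > 0, fs, 1.0)
    ds = np.where(ds > 0, ds, 1.0)
    X = (F - fm) / fs
    Y = (D - dm) / ds
    Sxx = X.T @ X / (n - 1)
    Syy = Y.T @ Y / (n - 1)
    Sxy = X.T @ Y / (n - 1)
    Wx = _inv_sqrt(Sxx, ridge)
    Wy = _inv_sqrt(Syy, ridge)
    A, s, Bt = svd(Wx @ Sxy @ Wy, full_matrices=False)
    k = min(k, len(s))
    U = Wx @ A[:, :k]
    V = Wy @ Bt.T[:, :k]
    corr = np.clip(s[:k], 0.0, 1.0)
    # sign convention
    for j in range(k):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    return EnsembleModel(
        U=U, V=V, correlations=corr,
        feature_means=fm, feature_sds=fs, ddm_means=dm, ddm_sds=ds,
    )


def label_components(model: EnsembleModel) -> EnsembleModel:
    """Assign the choice / responsiveness / pliancy labels (a bijection).

    choice: largest combined mass on difference features and on v.
    responsiveness: of the rest, a and t loadings share sign.
    pliancy: of the rest, a and t loadings have opposite signs.
    """
    k = model.U.shape[1]
    if k != 3:
        raise ValueError("labeling requires exactly 3 components")
    diff_rows = [i for i, name in enumerate(FEATURE_NAMES) if name.endswith("_diff")]
    i_a, i_v, i_t = DDM_COLUMNS.index("a"), DDM_COLUMNS.index("v"), DDM_COLUMNS.index("t")

    def diff_mass(j: int) -> float:
        u = np.abs(model.U[:, j])
        tot = u.sum()
        act = u[diff_rows].sum() / tot if tot > 0 else 0.0
        v = np.abs(model.V[:, j])
        vt = v.sum()
        ddm = v[i_v] / vt if vt > 0 else 0.0
        return act + ddm

    choice = int(np.argmax([diff_mass(j) for j in range(3)]))
    rest = [j for j in range(3) if j != choice]
    confident = True
    same_sign = [model.V[i_a, j] * model.V[i_t, j] > 0 for j in rest]
    if same_sign[0] == same_sign[1]:
        # ambiguous: fall back to the magnitude of the a*t product
        confident = False
        prods = [model.V[i_a, j] * model.V[i_t, j] for j in rest]
        resp = rest[int(np.argmax(prods))]
    else:
        resp = rest[0] if same_sign[0] else rest[1]
    pli = [j for j in rest if j != resp][0]
    model.labels = {"choice": choice, "responsiveness": resp, "pliancy": pli}
    model.label_confident = confident
    return model


# --------------------------------------------------------------------- #
# drive time series
# --------------------------------------------------------------------- #

@dataclass
class DriveSeries:
    """Backward-aligned control-ensemble drives per decision group.

    For each group ('fast_left', 'fast_right', 'slow_left', 'slow_right'):
    `aligned_bins` indexes bins backward from the decision (0 = decision
    bin, -1 = one bin earlier, ...); `mean` and `sd` are
    (n_bins x 3) cumulative drives in percent of the group's pre-stimulus
    feature magnitude, columns ordered as model components.
    """

    groups: dict = field(default_factory=dict)
    component_labels: dict = field(default_factory=dict)

    def group(self, name: str) -> dict:
        return self.groups[name]


def trial_drives(rates: np.ndarray, stim_onset_bin: int, model: EnsembleModel) -> np.ndarray:
    """Per-bin drive increments W_k (n_bins x k) for one trial.

    Increments use the feature change between consecutive bins from
    stimulus onset to the decision bin, in standardized feature units; the
    onset bin's increment is zero by the baseline convention.
    """
    feats = np.array([feature_vector_from_means(rates[:, j])
                      for j in range(rates.shape[1])])
    seg = feats[stim_onset_bin:]
    dF = np.zeros_like(seg)
    dF[1:] = seg[1:] - seg[:-1]
    return model.scale_features(dF) @ model.U


def drive_timeseries(trace_set, model: EnsembleModel, tertiles: DtTertiles,
                     max_bins: int | None = None) -> DriveSeries:
    """Group-averaged cumulative drive time series, aligned backward from
    the decision time.

    Fast/slow groups are the first/third decision-time tertiles; trials in
    the middle tertile are not used.  Cumulative drives are expressed as a
    percentage of the norm of each group's mean pre-stimulus standardized
    feature vector.
    """
    per_group: dict[str, list] = {f"{s}_{c}": [] for s in ("fast", "slow")
                                  for c in ("left", "right")}
    base_norms: dict[str, list] = {g: [] for g in per_group}
    for _, trials in trace_set:
        for t in trials:
            if t.timed_out or t.choice == "none":
                continue
            speed = tertiles.classify(t.decision_time)
            if speed == "intermediate":
                continue
            seg = t.decision_rates()
            if seg.shape[1] - t.stim_onset_bin < 2:
                warnings.warn(f"trial {t.trial_id} shorter than 2 bins; excluded")
                continue
            g = f"{speed}_{t.choice}"
            W = trial_drives(seg, t.stim_onset_bin, model)
            per_group[g].append(np.cumsum(W, axis=0))
            pre = seg[:, : t.stim_onset_bin]
            if pre.shape[1] > 0:
                fv = model.scale_features(feature_vector_from_means(pre.mean(axis=1)))
                base_norms[g].append(np.linalg.norm(fv))

    series = DriveSeries(component_labels=dict(model.labels))
    for g, trials_w in per_group.items():
        if not trials_w:
            continue
        L = max(len(w) for w in trials_w)
        if max_bins is not None:
            L = min(L, max_bins)
        k = model.U.shape[1]
        acc = np.full((len(trials_w), L, k), np.nan)
        for i, w in enumerate(trials_w):
            m = min(len(w), L)
            acc[i, L - m:] = w[-m:]
        mean = np.nanmean(acc, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(acc, axis=0)
        norm = np.mean(base_norms[g]) if base_norms[g] else 1.0
        norm = norm if norm > 0 else 1.0
        series.groups[g] = {
            "aligned_bins": np.arange(-L + 1, 1),
            "mean": 100.0 * mean / norm,
            "sd": 100.0 * sd / norm,
            "n_trials": len(trials_w),
        }
    return series


def drive_onset_bins(series: DriveSeries, group: str, frac: float = 0.2) -> dict:
    """Onset timing of each ensemble's group-mean cumulative drive.

    The onset is the earliest aligned bin from which the curve departs
    toward its final value and stays there: at every later bin it shares
    the sign of the final value and exceeds ``frac`` of its magnitude.
    Earlier (more negative) means an earlier response.
    """
    g = series.group(group)
    mean = g["mean"]
    bins = g["aligned_bins"]
    out = {}
    for label, j in series.component_labels.items():
        curve = mean[:, j]
        final = curve[-1]
        if not np.isfinite(final) or final == 0:
            out[label] = int(bins[-1])
            continue
        committed = (np.sign(curve) == np.sign(final)) & (
            np.abs(curve) >= frac * abs(final)
        )
        onset = len(curve) - 1
        for b in range(len(curve) - 1, -1, -1):
            if committed[b]:
                onset = b
            else:
                break
        out[label] = int(bins[onset])
    return out


# --------------------------------------------------------------------- #
# zone projections
# --------------------------------------------------------------------- #

@dataclass
class ZoneProjection:
    """Predicted DDM-parameter changes per zone transition.

    For each ordered zone pair (i, j): W is (p x 3) ensemble drives and P
    is (p x 4) standardized DDM-parameter changes over the p networks that
    exhibit the direct transition; medians and percentage changes
    (relative to each network's fitted static parameter) summarize them.
    """

    pairs: dict = field(default_factory=dict)

    def to_records(self) -> list[dict]:
        recs = []
        for (zi, zj), d in sorted(self.pairs.items()):
            for c, name in enumerate(DDM_COLUMNS):
                recs.append({
                    "zone_from": zi, "zone_to": zj, "parameter": name,
                    "median_change": d["median_change"][c],
                    "pct_change": d["pct_change"][c],
                    "n_networks": d["n_networks"],
                })
        return recs


def network_zone_features(trials: list, sequences: list, partition: ZonePartition) -> tuple[dict, set]:
    """Zone-mean feature vectors and the set of observed direct zone
    transitions for one network.

    Features are averaged over all bins whose state lies in each zone,
    pooled across the network's non-timeout trials.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    transitions: set[tuple[str, str]] = set()
    seq_by_id = {s.trial_id: s for s in sequences}
    for t in trials:
        if t.timed_out or t.trial_id not in seq_by_id:
            continue
        seq = seq_by_id[t.trial_id]
        seg = t.decision_rates()
        zones = [partition.zone_of(int(s)) for s in seq.labels]
        for j, z in enumerate(zones):
            fv = feature_vector_from_means(seg[:, j])
            sums[z] = sums.get(z, 0) + fv
            counts[z] = counts.get(z, 0) + 1
        for za, zb in zip(zones[:-1], zones[1:]):
            if za != zb and za != "unassigned" and zb != "unassigned":
                transitions.add((za, zb))
    means = {z: sums[z] / counts[z] for z in sums if counts[z] > 0}
    return means, transitions


def zone_projection(trace_set, sequences_per_network: list,
                    partition: ZonePartition, model: EnsembleModel,
                    ddm_table: np.ndarray) -> ZoneProjection:
    """Project zone-transition activity changes into DDM-parameter changes.

    ddm_table is (n_networks x 4) of fitted static parameters aligned with
    trace_set.  For each zone pair, only networks where the direct
    transition occurs contribute; pairs observed in no network are
    omitted.
    """
    per_network = []
    for (cfg, trials), seqs in zip(trace_set, sequences_per_network):
        per_network.append(network_zone_features(trials, seqs, partition))

    pair_rows: dict[tuple[str, str], list] = {}
    pair_nets: dict[tuple[str, str], list] = {}
    for p, (means, transitions) in enumerate(per_network):
        for (zi, zj) in transitions:
            if zi in means and zj in means:
                pair_rows.setdefault((zi, zj), []).append(means[zj] - means[zi])
                pair_nets.setdefault((zi, zj), []).append(p)

    proj = ZoneProjection()
    for pair, rows in pair_rows.items():
        dF = model.scale_features(np.array(rows))
        W = dF @ model.U                      # (p, 3)
        P_std = W @ model.V.T                 # (p, 4), standardized units
        P = P_std * model.ddm_sds             # raw parameter units
        nets = pair_nets[pair]
        base = ddm_table[nets]                # (p, 4)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * P / np.abs(base)
        proj.pairs[pair] = {
            "W": W,
            "P": P,
            "median_drive": np.median(W, axis=0),
            "median_change": np.median(P, axis=0),
            "pct_change": np.median(pct, axis=0),
            "n_networks": len(nets),
        }
    return proj
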