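"""Seeded synthetic-data generators with known ground truth.

The study's raw field data (measurement supplements, stream count sheets)
are not published, so every pipeline input can instead be simulated with the
truth recorded alongside: sequence sets at controlled pairwise divergence,
morphometric records drawn inside a chosen cluster's trait ranges, multinomial
microhabitat counts with known availability and preference, and a
stream x habitat-variable matrix with a planted low-rank factor structure.
Defaults mirror the study scale (33 stream sections, 8 microhabitats, 3 focal
species, ~550 bp barcode fragments).  All generators are deterministic under a
fixed seed and return (data, truth) pairs consumed by the recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .barcode import SequenceRecord
from .ecology import MICROHABITATS, MicrohabitatTable
from .guilds import ClusterRuleSet, builtin_cluster_rules
from .morphometrics import MeasurementRecord

__all__ = [
    "generate_sequences",
    "generate_morphometrics",
    "generate_community",
    "generate_habitat_matrix",
]

_BASES = np.array(list("ACGT"))

#: printed body-length span of the rheophilous vouchers (mm)
_BL_RANGE = (6.0, 13.5)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_sequences(
    base_length: int = 550,
    divergences: Sequence[float] = (0.03, 0.07, 0.12),
    n_per_level: int = 1,
    seed: int = 0,
    indel_rate: float = 0.0,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """A random base sequence plus derivatives at controlled divergence.

    Substitutions are uniform over the three alternative bases (a
    Jukes-Cantor-like process, appropriate because identities are raw percent
    matches, not model-corrected distances), planted independently per site at
    the requested expected proportion.  ``indel_rate`` optionally deletes
    single sites at that per-site rate.  The truth table records the realized
    number of substitutions for every derived sequence.
    """
    for d in divergences:
        if not 0 <= d <= 0.25:
            raise ValueError(f"divergence {d} outside [0, 0.25]")
    rng = _rng(seed)
    base = "".join(rng.choice(_BASES, size=base_length))
    records = [SequenceRecord(id="base", sequence=base, role="adult_reference",
                              reference_status="described_species")]
    truth_rows = []
    for li, d in enumerate(divergences):
        for k in range(n_per_level):
            seq = np.array(list(base))
            hit = rng.random(base_length) < d
            n_sub = int(hit.sum())
            for pos in np.flatnonzero(hit):
                alternatives = [b for b in "ACGT" if b != seq[pos]]
                seq[pos] = rng.choice(alternatives)
            if indel_rate > 0:
                keep = rng.random(len(seq)) >= indel_rate
                seq = seq[keep]
            sid = f"div{li}_{k}"
            records.append(
                SequenceRecord(id=sid, sequence="".join(seq), role="tadpole_query")
            )
            truth_rows.append(
                {
                    "id": sid,
                    "requested_divergence": d,
                    "realized_substitutions": n_sub,
                    "realized_proportion": n_sub / base_length,
                    "length": int(len(seq)),
                }
            )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# morphometric records inside a cluster's trait envelope

_CLUSTER2_STYLES = {
    # upper sheath present, the wider-gap LTRF patterns
    "albipunctatus": {"sheath": True, "ltrf": ("8(5–8)/3", "7(5–7)/3")},
    # upper sheath always absent, the unique 8(6-8)/3 formula
    "mandraka": {"sheath": False, "ltrf": ("8(6–8)/3",)},
}


def _rule_for(cluster_id: int, rules) -> ClusterRuleSet:
    for rule in rules:
        if rule.cluster_id == cluster_id:
            return rule
    raise ValueError(f"cluster_id must be 1, 2 or 3, got {cluster_id}")


def _soft_range(rule: ClusterRuleSet, name: str) -> Optional[tuple[float, float]]:
    for sr in rule.soft:
        if sr.name == name:
            return sr.low, sr.high
    return None


def _draw_inside(rng, lo: float, hi: float, margin: float) -> float:
    pad = (hi - lo) * margin
    return rng.uniform(lo + pad, hi - pad)


def generate_morphometrics(
    cluster_id: int,
    n: int = 20,
    jitter: float = 0.0,
    seed: int = 0,
    style: Optional[str] = None,
    margin: float = 0.05,
) -> tuple[list[MeasurementRecord], pd.DataFrame]:
    """Voucher-like records drawn strictly inside one cluster's rule envelope.

    Ratios are sampled uniformly inside each soft range (shrunk by ``margin``
    of the range width at each end) and absolute measurements back-solved from
    a body length in the observed 6.0-13.5 mm span; categorical traits and the
    LTRF follow the cluster's hard constraints.  With probability ``jitter``
    a record gets exactly one ratio displaced outside its range (past the
    classifier's tolerance), so a jitter of 0.1 leaves ~10% of records with a
    soft score below 1.  The truth table carries the cluster label, the
    cluster-2 style, and which constraint (if any) was displaced.
    """
    rules = builtin_cluster_rules()
    rule = _rule_for(cluster_id, rules)
    rng = _rng(seed)
    records: list[MeasurementRecord] = []
    truth_rows = []
    for i in range(n):
        if cluster_id == 2:
            chosen_style = style or rng.choice(list(_CLUSTER2_STYLES))
            style_spec = _CLUSTER2_STYLES[chosen_style]
            sheath = style_spec["sheath"]
            ltrf = str(rng.choice(style_spec["ltrf"]))
            margin_state = str(rng.choice(["shallow_crevice", "free"]))
        else:
            chosen_style = ""
            sheath = rule.requires_upper_sheath
            ltrf = str(rng.choice(rule.allowed_ltrf))
            margin_state = rule.allowed_margins[0]

        bl = rng.uniform(*_BL_RANGE)
        bw = bl * rng.uniform(0.30, 0.40)
        bh = bl * rng.uniform(0.25, 0.35)
        np_dist = bl * rng.uniform(0.08, 0.14)  # naris-pupil distance

        ratios: dict[str, float] = {}
        for name in ("ODW/BW", "A1len/ODW", "JW/ODW", "MCL/JW", "DG/BW",
                     "SE/BL", "RN/NP", "TAL/BL"):
            span = _soft_range(rule, name)
            if span is not None:
                ratios[name] = _draw_inside(rng, *span, margin)
        # the eye/naris height ratios are linked (NH/BH = EH/BH x NH/EH / 100):
        # rejection-sample the triple so all three land in range
        eh_span = _soft_range(rule, "EH/BH")
        ne_span = _soft_range(rule, "NH/EH")
        nb_span = _soft_range(rule, "NH/BH")
        for _ in range(1000):
            eh_bh = _draw_inside(rng, *eh_span, margin)
            nh_eh = _draw_inside(rng, *ne_span, margin)
            nh_bh = eh_bh * nh_eh / 100.0
            lo, hi = nb_span
            pad = (hi - lo) * margin
            if lo + pad <= nh_bh <= hi - pad:
                break
        else:  # pragma: no cover - ranges always overlap for the builtin rules
            raise RuntimeError("could not satisfy the eye/naris ratio ranges")
        ratios["EH/BH"], ratios["NH/EH"], ratios["NH/BH"] = eh_bh, nh_eh, nh_bh

        counts: dict[str, int] = {}
        for name in ("A1num", "MP", "SMP"):
            span = _soft_range(rule, name)
            if span is not None:
                counts[name] = int(rng.integers(int(span[0]), int(span[1]) + 1))

        displaced = ""
        if jitter > 0 and rng.random() < jitter:
            candidates = [k for k in ratios if k != "NH/BH"]
            displaced = str(rng.choice(candidates))
            lo, hi = _soft_range(rule, displaced)
            width = hi - lo
            # past the upper bound by more than the classifier's +/-2-point
            # ratio tolerance
            ratios[displaced] = hi + 2.0 + 1.0 + rng.uniform(0, 0.2 * width)

        m: dict[str, float] = {"BL": bl, "BW": bw, "BH": bh, "NP": np_dist}
        m["ODW"] = ratios["ODW/BW"] / 100 * bw
        m["A1len"] = ratios["A1len/ODW"] / 100 * m["ODW"]
        m["JW"] = ratios["JW/ODW"] / 100 * m["ODW"]
        if "MCL/JW" in ratios:
            m["MCL"] = ratios["MCL/JW"] / 100 * m["JW"]
        if "DG/BW" in ratios:
            m["DG"] = ratios["DG/BW"] / 100 * bw
        m["EH"] = ratios["EH/BH"] / 100 * bh
        m["NH"] = ratios["NH/EH"] / 100 * m["EH"]
        m["SE"] = ratios["SE/BL"] / 100 * bl
        m["RN"] = ratios["RN/NP"] / 100 * np_dist
        m["TAL"] = ratios["TAL/BL"] / 100 * bl
        m["TL"] = bl + m["TAL"]
        m.update(counts)

        rec = MeasurementRecord(
            voucher_id=f"sim-c{cluster_id}-{i:03d}",
            species_label=f"synthetic cluster {cluster_id}",
            gosner_stage=int(rng.integers(25, 37)),
            measurements=m,
            has_dorsal_gap=rule.requires_dorsal_gap,
            has_upper_jaw_sheath=sheath,
            oral_disc_margin=margin_state,
            ltrf=ltrf,
        )
        # keep the gap flag and DG measurement consistent for cluster 3
        if rule.requires_dorsal_gap is False:
            rec.measurements.pop("DG", None)
        records.append(rec)
        truth_rows.append(
            {
                "voucher_id": rec.voucher_id,
                "cluster": cluster_id,
                "style": chosen_style,
                "ltrf": ltrf,
                "displaced_constraint": displaced,
            }
        )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# stream communities

@dataclass
class CommunityTruth:
    availability: pd.DataFrame            # stream x microhabitat
    cell_probabilities: pd.DataFrame      # (stream, species) x microhabitat
    expected_E: pd.DataFrame              # analytic E per cell


def generate_community(
    n_streams: int = 33,
    species: Sequence[str] = ("sp_A", "sp_B", "sp_C"),
    preference_weights: Optional[dict[str, Sequence[float]]] = None,
    availability: Optional[Sequence[float]] = None,
    mean_abundance: float = 10.0,
    seed: int = 0,
) -> tuple[MicrohabitatTable, CommunityTruth]:
    """Multinomial microhabitat counts with known availability and preference.

    Per stream and species the specimen total is Poisson(``mean_abundance``)
    and the specimens fall into the 8 microhabitats with probabilities
    proportional to availability x preference weight.  Availability is either
    the supplied fixed vector or an independent Dirichlet draw per stream.
    The truth carries the analytic electivity E = (r* - p)/(r* + p) with
    r* the normalised availability-weighted preference.
    """
    rng = _rng(seed)
    if preference_weights is None:
        preference_weights = {sp: np.ones(len(MICROHABITATS)) for sp in species}
    weights = {}
    for sp in species:
        w = np.asarray(preference_weights[sp], dtype=float)
        if w.shape != (len(MICROHABITATS),):
            raise ValueError(f"weights for {sp} must have length {len(MICROHABITATS)}")
        if (w < 0).any():
            raise ValueError("preference weights must be >= 0")
        if w.sum() == 0:
            raise ValueError(f"all-zero preference weights for {sp}")
        weights[sp] = w

    streams = [f"stream{i + 1:02d}" for i in range(n_streams)]
    if availability is not None:
        avail_matrix = np.tile(np.asarray(availability, dtype=float), (n_streams, 1))
    else:
        avail_matrix = rng.dirichlet(np.full(len(MICROHABITATS), 3.0), size=n_streams)
    avail = pd.DataFrame(avail_matrix, index=streams, columns=list(MICROHABITATS))

    index = pd.MultiIndex.from_product(
        [streams, list(species)], names=["stream", "species"]
    )
    counts = pd.DataFrame(0, index=index, columns=list(MICROHABITATS))
    probs = pd.DataFrame(0.0, index=index, columns=list(MICROHABITATS))
    for stream in streams:
        p = avail.loc[stream].to_numpy()
        for sp in species:
            cell = p * weights[sp]
            cell = cell / cell.sum()
            probs.loc[(stream, sp)] = cell
            total = int(rng.poisson(mean_abundance)) if mean_abundance > 0 else 0
            if total > 0:
                counts.loc[(stream, sp)] = rng.multinomial(total, cell)

    p_broadcast = avail.reindex(index.get_level_values("stream")).set_axis(index)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = (probs - p_broadcast) / (probs + p_broadcast)
    expected = expected.where((probs + p_broadcast) > 0)
    table = MicrohabitatTable(counts=counts, availability=avail)
    return table, CommunityTruth(
        availability=avail, cell_probabilities=probs, expected_E=expected
    )


# ---------------------------------------------------------------------------
# habitat matrices with planted factor structure

@dataclass
class HabitatTruth:
    loadings: pd.DataFrame   # variables x factors
    factors: pd.DataFrame    # streams x factors
    noise_scale: float = dataclass_field(default=0.0)


def generate_habitat_matrix(
    n_streams: int = 33,
    n_vars: int = 10,
    n_factors: int = 2,
    loading_scale: float = 1.0,
    noise: float = 0.3,
    seed: int = 0,
    factor_decay: float = 0.7,
) -> tuple[pd.DataFrame, HabitatTruth]:
    """Stream x habitat-variable matrix with a planted low-rank correlation.

    ``X = F L' + noise``.  Factor scores are drawn standard-normal and then
    exactly orthogonalised (centred, QR, unit variance) and the loading
    columns are orthogonal with distinct norms (factor k shrinks by
    ``factor_decay**k``): a planted factor basis is identifiable by PCA only
    up to rotation of its span unless the factors are uncorrelated in-sample
    and of distinct strength, so the generator enforces exactly that.
    Variables carry generic names (the habitat-variable definitions live in
    the companion community study, not here).
    """
    if n_factors >= n_vars:
        raise ValueError("n_factors must be < n_vars")
    if not 0 < factor_decay <= 1:
        raise ValueError("factor_decay must be in (0, 1]")
    rng = _rng(seed)
    F = rng.standard_normal((n_streams, n_factors))
    F = F - F.mean(axis=0)
    Q, _ = np.linalg.qr(F)
    F = Q * np.sqrt(n_streams - 1)  # exactly uncorrelated, unit variance
    # loading columns: constant magnitude, mutually orthogonal random sign
    # patterns -> equal per-variable variance, so the correlation rescaling
    # leaves the planted directions untouched
    signs = np.empty((n_vars, n_factors))
    signs[:, 0] = rng.choice([-1.0, 1.0], size=n_vars)
    for k in range(1, n_factors):
        for _ in range(5000):
            candidate = rng.choice([-1.0, 1.0], size=n_vars)
            if np.all(np.abs(signs[:, :k].T @ candidate) < 1e-9):
                signs[:, k] = candidate
                break
        else:
            raise ValueError(
                f"cannot build {n_factors} orthogonal sign patterns over "
                f"{n_vars} variables"
            )
    strengths = factor_decay ** np.arange(n_factors)
    L = signs * 0.8 * loading_scale * strengths
    X = F @ L.T + noise * rng.standard_normal((n_streams, n_vars))
    streams = [f"stream{i + 1:02d}" for i in range(n_streams)]
    var_names = [f"habitat_var{j + 1:02d}" for j in range(n_vars)]
    factor_names = [f"factor{k + 1}" for k in range(n_factors)]
    matrix = pd.DataFrame(X, index=streams, columns=var_names)
    truth = HabitatTruth(
        loadings=pd.DataFrame(L, index=var_names, columns=factor_names),
        factors=pd.DataFrame(F, index=streams, columns=factor_names),
        noise_scale=noise,
    )
    return matrix, truth
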