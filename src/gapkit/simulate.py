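"""Synthetic data with known ground truth for every pipeline stage.

Generates (i) a reference gene family: a stop-free coding root sequence,
cluster ancestors produced by synonymous-biased substitution, and leaf
references per cluster; (ii) sample communities whose cluster abundances
follow a Gaussian niche response to a simulated soil pH gradient with
lognormal noise; (iii) paired-end reads with positional quality decay,
per-base substitution errors at the rate implied by the emitted quality,
and optional two-parent chimeras formed before reading. Truth tables
record each read's source template, cluster and chimera status.

All randomness flows from one seeded generator. Substitution-only errors
by default; indels are available to exercise frameshift sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .derep_denoise import reverse_frame_offset, stop_codons
from .formats_io import ReferenceDB, ReferenceEntry
from .pair_join import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = stop_codons()
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generator.

    Defaults emulate the bacterial amplicon setting: a 448-bp amplicon
    sequenced as 2 x 300-bp pairs over 7 soil samples at depth 5000, with
    a soil pH gradient spanning 3.5-8.5 driving cluster abundances.
    """

    n_clusters: int = 8
    refs_per_cluster: int = 2
    amplicon_len: int = 448
    within_cluster_div: float = 0.01
    between_cluster_div: float = 0.10
    read_len: int = 300
    n_samples: int = 7
    depth: int = 5000
    #: mean Phred at read start / end (linear decay along the read)
    q_start: int = 38
    q_end_fwd: int = 28
    q_end_rev: int = 22
    q_sd: float = 2.0
    #: emit substitution errors at the per-base rate 10^(-Q/10)
    apply_errors: bool = True
    indel_rate: float = 0.0
    chimera_rate: float = 0.01
    ph_range: tuple[float, float] = (3.5, 8.5)
    gradient_strength: float = 1.0
    abundance_noise_sd: float = 0.5
    #: truncation length of gap-mode mates (fixes the gap junction)
    gap_seg_len: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.within_cluster_div, self.between_cluster_div):
            if not 0 <= d < 0.5:
                raise ValueError("divergences must be in [0, 0.5)")
        for rate in (self.chimera_rate, self.indel_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must be in [0, 1)")
        if self.amplicon_len < 3:
            raise ValueError("amplicon_len must be >= 3")


def preset(name: str, **overrides) -> SimConfig:
    """Named study-condition presets.

    ``bacterial448``: 448-bp amplicon, assembleable from truncated 229-bp
    mates with a 10-base overlap. ``archaeal629``: 629-bp amplicon, longer
    than two mates, processable only by the gap pipeline.
    """
    if name == "bacterial448":
        return SimConfig(amplicon_len=448, **overrides)
    if name == "archaeal629":
        return SimConfig(amplicon_len=629, **overrides)
    raise ValueError(f"unknown preset {name!r}")


def _translate_stop_free(seq: str) -> bool:
    return not any(
        seq[i : i + 3] in _STOPS for i in range(0, len(seq) - 2, 3)
    )


def _mutate(seq: str, div: float, rng: np.random.Generator,
            mutable_region: tuple[int, int] | None = None) -> str:
    """Apply ~div substitutions/site, 3rd codon positions 3x more likely
    (a crude synonymous bias), resampling to keep frame-0 stop-freedom."""
    L = len(seq)
    lo, hi = mutable_region if mutable_region else (0, L)
    span = hi - lo
    n_sub = int(round(div * L))
    if n_sub == 0:
        return seq
    if n_sub > span:
        raise ValueError("mutable region too small for requested divergence")
    weights = np.ones(span)
    pos_range = np.arange(lo, hi)
    weights[pos_range % 3 == 2] = 3.0
    weights /= weights.sum()
    for _ in range(100):
        positions = rng.choice(pos_range, size=n_sub, replace=False, p=weights)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        for p in positions:
            choices = _BASES[_BASES != arr[p]]
            arr[p] = rng.choice(choices)
        cand = arr.tobytes().decode()
        if _translate_stop_free(cand):
            return cand
    raise RuntimeError(
        "could not preserve the stop-free property at this divergence"
    )


def simulate_references(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    mutable_region: tuple[int, int] | None = None,
) -> ReferenceDB:
    """Generate a clustered, stop-free reference database.

    ``mutable_region`` confines every substitution to a template window,
    which lets tests place cluster-diagnostic sites inside or outside the
    gap pipeline's unsequenced region.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_codons = -(-config.amplicon_len // 3)
    root = "".join(rng.choice(_CODONS) for _ in range(n_codons))
    root = root[: config.amplicon_len]
    if not _translate_stop_free(root):  # trailing partial codon is safe
        raise RuntimeError("root construction produced a stop codon")
    entries = []
    for k in range(config.n_clusters):
        ancestor = _mutate(root, config.between_cluster_div, rng,
                           mutable_region)
        for i in range(config.refs_per_cluster):
            leaf = (
                _mutate(ancestor, config.within_cluster_div, rng,
                        mutable_region)
                if config.within_cluster_div > 0
                else ancestor
            )
            entries.append(
                ReferenceEntry(f"C{k + 1}R{i + 1}", f"C{k + 1}", leaf)
            )
    rev_off = reverse_frame_offset(config.amplicon_len, config.gap_seg_len)
    return ReferenceDB(entries, frame_offset=0, rev_frame_offset=rev_off)


def simulate_community(
    refdb: ReferenceDB,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample true relative cluster abundances plus an env table.

    Cluster log-abundance follows a Gaussian niche model on pH:
    log a = -gradient_strength * (pH_s - optimum_k)^2 + lognormal noise,
    with cluster optima evenly spaced across the pH range. With
    gradient_strength 0 the abundances are exchangeable across samples.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    clusters = refdb.cluster_labels
    lo, hi = config.ph_range
    ph = np.sort(rng.uniform(lo, hi, size=config.n_samples))
    optima = np.linspace(lo, hi, len(clusters))
    log_ab = (
        -config.gradient_strength * (ph[:, None] - optima[None, :]) ** 2
        + rng.normal(0.0, config.abundance_noise_sd,
                     size=(config.n_samples, len(clusters)))
    )
    ab = np.exp(log_ab)
    ab /= ab.sum(axis=1, keepdims=True)
    sample_ids = [f"S{i + 1}" for i in range(config.n_samples)]
    abund = pd.DataFrame(ab, index=sample_ids, columns=clusters)

    carbon = np.exp(rng.normal(1.0, 0.5, config.n_samples))
    cn = rng.uniform(8.5, 22.1, config.n_samples)
    nitrogen = carbon / cn
    env = pd.DataFrame(
        {
            "pH": ph,
            "C": carbon,
            "N": nitrogen,
            "C:N": cn,
            "moisture": rng.uniform(14.2, 75.1, config.n_samples),
            "LOI": carbon * rng.uniform(1.5, 2.5, config.n_samples),
            "vegetation": rng.choice(
                ["grassland", "forest", "agricultural", "moorland"],
                size=config.n_samples,
            ),
        },
        index=sample_ids,
    )
    return abund, env


@dataclass
class SimulatedSample:
    sample_id: str
    reads: list  # of formats_io.PairedRead
    truth: pd.DataFrame  # read_id, template_id, cluster, is_chimera


def _quality_matrix(n: int, read_len: int, q_start: int, q_end: int,
                    q_sd: float, rng: np.random.Generator) -> np.ndarray:
    mean = np.linspace(q_start, q_end, read_len)
    q = rng.normal(mean, q_sd, size=(n, read_len))
    return np.clip(np.rint(q), 2, 41).astype(np.int64)


def _apply_substitutions(seqs: np.ndarray, quals: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    p_err = 10.0 ** (-quals / 10.0)
    mask = rng.random(seqs.shape) < p_err
    if mask.any():
        shift = rng.integers(1, 4, size=int(mask.sum()))
        originals = seqs[mask]
        # rotate within ACGT so the substituted base always differs
        idx = np.searchsorted(_BASES, originals)
        seqs = seqs.copy()
        seqs[mask] = _BASES[(idx + shift) % 4]
    return seqs


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(ch)
        if rate / 2 <= r < rate:
            out.append("ACGT"[rng.integers(4)])  # insertion
    return "".join(out)


def simulate_reads(
    community: pd.DataFrame,
    refdb: ReferenceDB,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SimulatedSample]:
    """Draw paired-end reads per sample from the true community.

    Templates are drawn by abundance (split evenly across a cluster's
    references); with probability ``chimera_rate`` a read derives from a
    splice of two drawn templates at a uniform breakpoint. Substitution
    errors occur at the per-base rate implied by the simulated quality
    when ``apply_errors`` is on; the error-free setting still emits
    realistic quality strings but introduces no errors.
    """
    from .formats_io import PairedRead  # local import to avoid cycles

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    templates = [e.sequence for e in refdb.entries]
    template_ids = [e.ref_id for e in refdb.entries]
    template_cluster = [e.cluster_label for e in refdb.entries]
    clusters = refdb.cluster_labels
    per_ref_weight = {
        c: 1.0 / sum(1 for lab in template_cluster if lab == c)
        for c in clusters
    }
    probs_by_template = np.array([
        [community.loc[s, template_cluster[t]] * per_ref_weight[template_cluster[t]]
         for t in range(len(templates))]
        for s in community.index
    ])
    probs_by_template /= probs_by_template.sum(axis=1, keepdims=True)

    out = []
    L = config.amplicon_len
    rl = min(config.read_len, L)
    for si, sample_id in enumerate(community.index):
        draws = rng.choice(len(templates), size=config.depth,
                           p=probs_by_template[si])
        chim_mask = rng.random(config.depth) < config.chimera_rate

        fq = _quality_matrix(config.depth, rl, config.q_start,
                             config.q_end_fwd, config.q_sd, rng)
        rq = _quality_matrix(config.depth, rl, config.q_start,
                             config.q_end_rev, config.q_sd, rng)
        reads, truth_rows = [], []
        for i in range(config.depth):
            t = int(draws[i])
            tmpl, is_chim, tid = templates[t], False, template_ids[t]
            if chim_mask[i] and len(set(templates)) > 1:
                # redraw until the splice is a genuine chimera, so that
                # chimera_rate is the realised chimeric-read fraction
                for _ in range(20):
                    p = int(rng.choice(len(templates),
                                       p=probs_by_template[si]))
                    b = int(rng.integers(1, L))
                    cand = templates[t][:b] + templates[p][b:]
                    if cand not in templates:
                        tmpl, is_chim = cand, True
                        tid = f"{template_ids[t]}x{template_ids[p]}@{b}"
                        break
            if config.indel_rate > 0:
                tmpl = _apply_indels(tmpl, config.indel_rate, rng)
            fwd = np.frombuffer(tmpl[:rl].encode(), dtype=np.uint8)
            rev = np.frombuffer(
                reverse_complement(tmpl)[:rl].encode(), dtype=np.uint8
            )
            if config.apply_errors:
                fwd = _apply_substitutions(fwd, fq[i], rng)
                rev = _apply_substitutions(rev, rq[i], rng)
            read_id = f"{sample_id}_r{i + 1}"
            reads.append(PairedRead(
                read_id,
                fwd.tobytes().decode(), tuple(int(x) for x in fq[i]),
                rev.tobytes().decode(), tuple(int(x) for x in rq[i]),
            ))
            truth_rows.append({
                "read_id": read_id,
                "template_id": tid,
                "cluster": template_cluster[t],
                "is_chimera": is_chim,
            })
        out.append(SimulatedSample(sample_id, reads,
                                   pd.DataFrame(truth_rows)))
    return out


def error_free(config: SimConfig) -> SimConfig:
    """The exact-recovery setting: flat Q40 qualities, no substitutions,
    no chimeras, no indels."""
    return replace(config, apply_errors=False, chimera_rate=0.0,
                   indel_rate=0.0, q_start=40, q_end_fwd=40, q_end_rev=40,
                   q_sd=0.0)
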