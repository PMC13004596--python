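"""Seeded generators for every pipeline input, with machine-readable truth.

Each generator is a pure function of its parameters and seed. One global
seed expands to fixed per-component substreams (via ``SeedSequence`` spawn
keys), so adding a new generator never perturbs the outputs of existing
ones. Ground truth is returned alongside the data and can be serialized as
JSON with :func:`bscomp.io_formats.write_truth`.

Motif windows are made exactly scannable by rejection sampling: the random
background is redrawn until it contains neither a core nor a half-site
match, motifs are then planted, and the planted window is re-verified with
the production scanner, so per-window truth is exact rather than
approximate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence, IntronRecord
from .motifs import CORE_ACTAA, HALFSITE_YAAY, MotifPattern, classify_window, find_occurrences
from .splicing import CountMatrix

# fixed substream keys, one per generator
_STREAM_CONTRAST = 1
_STREAM_INTRONS = 2
_STREAM_COUNTS = 3
_STREAM_PROTEOMICS = 4

QUADRANTS = ("A_up_B_up", "A_up_B_down", "A_down_B_up", "A_down_B_down")
_QUADRANT_SIGNS = {
    "A_up_B_up": (1, 1),
    "A_up_B_down": (1, -1),
    "A_down_B_up": (-1, 1),
    "A_down_B_down": (-1, -1),
}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# contrast tables


def sim_contrast_tables(
    n_events: int = 200,
    quadrant_counts: tuple[int, int, int, int] = (30, 10, 5, 15),
    n_null: int = 2000,
    dpsi_magnitude: float = 25.0,
    mv_magnitude: float = 5.0,
    dpsi_min: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two contrast tables with planted quadrant structure.

    Co-regulated events get |dPSI| ~ U(dpsi_min+5, dpsi_min+dpsi_magnitude)
    in both contrasts (clear of the significance threshold), signs set by
    their quadrant, and MVdPSI95 > 0. Events beyond the quadrant total are
    significant in contrast A only (MVdPSI95 = 0 in B), so they are neither
    co-regulated nor eligible controls. Null events move <1 point, have
    MVdPSI95 = 0 and base mean > 100.
    """
    n_coreg = int(sum(quadrant_counts))
    if n_coreg > n_events:
        raise ValueError("quadrant counts exceed n_events")
    rng = _rng(seed, _STREAM_CONTRAST)

    rows_a, rows_b = [], []
    truth_events: dict[str, str] = {}
    idx = 0

    def _mag(n: int) -> np.ndarray:
        return rng.uniform(dpsi_min + 5, dpsi_min + dpsi_magnitude, n)

    for quadrant, count in zip(QUADRANTS, quadrant_counts):
        sa, sb = _QUADRANT_SIGNS[quadrant]
        mag_a, mag_b = _mag(count), _mag(count)
        for i in range(count):
            eid = f"E{idx:05d}"
            idx += 1
            truth_events[eid] = quadrant
            rows_a.append((eid, sa * mag_a[i], rng.uniform(0.5, mv_magnitude)))
            rows_b.append((eid, sb * mag_b[i], rng.uniform(0.5, mv_magnitude)))

    for _ in range(n_events - n_coreg):
        eid = f"E{idx:05d}"
        idx += 1
        truth_events[eid] = "single_contrast"
        sign = rng.choice([-1, 1])
        rows_a.append((eid, sign * rng.uniform(dpsi_min + 5, dpsi_min + dpsi_magnitude),
                       rng.uniform(0.5, mv_magnitude)))
        rows_b.append((eid, rng.uniform(-0.9, 0.9), 0.0))

    for _ in range(n_null):
        eid = f"E{idx:05d}"
        idx += 1
        truth_events[eid] = "null"
        rows_a.append((eid, rng.uniform(-0.9, 0.9), 0.0))
        rows_b.append((eid, rng.uniform(-0.9, 0.9), 0.0))

    base_mean = rng.uniform(150.0, 3000.0, idx)

    def _table(rows: list) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_id": [r[0] for r in rows],
                "gene_id": [f"G{i:05d}" for i in range(len(rows))],
                "event_type": "AltEX",
                "dpsi": [r[1] for r in rows],
                "mv_dpsi95": [r[2] for r in rows],
                "base_mean": base_mean,
            }
        )

    truth = {
        "quadrant_counts": dict(zip(QUADRANTS, (int(c) for c in quadrant_counts))),
        "events": truth_events,
        "n_null": int(n_null),
    }
    return _table(rows_a), _table(rows_b), truth


# ---------------------------------------------------------------------------
# intron windows and genomes


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _motif_free(rng, length, gc, core, halfsite, max_tries=500) -> str:
    for _ in range(max_tries):
        seq = _random_dna(rng, length, gc)
        if not find_occurrences(seq, core) and not find_occurrences(seq, halfsite):
            return seq
    raise RuntimeError(
        "rejection sampling failed to produce a motif-free window; "
        "try lower gc or a less degenerate motif"
    )


def _halfsite_instance(rng: np.random.Generator) -> str:
    return rng.choice(["C", "T"]) + "AA" + rng.choice(["C", "T"])


def _plant_window(
    rng: np.random.Generator,
    category: str,
    length: int,
    gc: float,
    core: MotifPattern,
    halfsite: MotifPattern,
    max_dist: int,
    max_tries: int = 200,
) -> tuple[str, list[int], list[int]]:
    """One window of the requested category; re-verified with the scanner."""
    core_len = len(core)
    core_str = core.pattern  # concrete for the default non-degenerate cores
    tandem = core_str + core_str[1:] if core_str.startswith("A") else core_str * 2
    for _ in range(max_tries):
        seq = list(_motif_free(rng, length, gc, core, halfsite))
        core_offsets: list[int] = []
        half_offsets: list[int] = []
        if category == "none":
            pass
        elif category == "core_only":
            pos = int(rng.integers(0, length - core_len + 1))
            seq[pos : pos + core_len] = core_str
            core_offsets = [pos]
        elif category == "bipartite":
            hs = _halfsite_instance(rng)
            gap = int(rng.integers(1, max_dist + 1))
            block = core_len + gap + len(hs)
            if block > length:
                raise ValueError("window too short for a bipartite plant")
            pos = int(rng.integers(0, length - block + 1))
            if rng.random() < 0.5:  # half-site downstream of core
                seq[pos : pos + core_len] = core_str
                hpos = pos + core_len + gap
                core_offsets = [pos]
            else:  # half-site upstream
                hpos = pos
                seq[pos + len(hs) + gap : pos + block] = core_str
                core_offsets = [pos + len(hs) + gap]
            seq[hpos : hpos + len(hs)] = hs
            half_offsets = [hpos]
        elif category == "dual_core":
            if rng.random() < 0.5 and len(tandem) <= length:
                pos = int(rng.integers(0, length - len(tandem) + 1))
                seq[pos : pos + len(tandem)] = tandem
                core_offsets = sorted(find_occurrences(tandem, core))
                core_offsets = [pos + o for o in core_offsets]
            else:
                gap = int(rng.integers(1, 15))
                block = 2 * core_len + gap
                pos = int(rng.integers(0, length - block + 1))
                seq[pos : pos + core_len] = core_str
                p2 = pos + core_len + gap
                seq[p2 : p2 + core_len] = core_str
                core_offsets = [pos, p2]
        else:
            raise ValueError(f"unknown category {category!r}")
        seq_str = "".join(seq)
        report = classify_window(seq_str, core=core, halfsite=halfsite, max_dist=max_dist)
        if report.category == category and report.core_offsets == core_offsets:
            return seq_str, core_offsets, half_offsets
    raise RuntimeError(f"failed to plant a clean {category} window after {max_tries} tries")


def sim_motif_windows(
    n: int,
    dual_rate: float = 0.18,
    bipartite_rate: float = 0.15,
    single_rate: float = 0.25,
    length: int = 80,
    gc: float = 0.4,
    core: MotifPattern = CORE_ACTAA,
    halfsite: MotifPattern = HALFSITE_YAAY,
    max_dist: int = 20,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    id_prefix: str = "w",
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Windows with planted motif categories at the given rates.

    Returns (windows, truth): windows as (id, sequence) pairs and one truth
    dict per window with its planted category and offsets.
    """
    if not 0 <= dual_rate + bipartite_rate + single_rate <= 1:
        raise ValueError("category rates must lie in [0, 1] and sum to at most 1")
    if rng is None:
        rng = _rng(seed, _STREAM_INTRONS)
    categories = rng.choice(
        ["dual_core", "bipartite", "core_only", "none"],
        size=n,
        p=[
            dual_rate,
            bipartite_rate,
            single_rate,
            1 - dual_rate - bipartite_rate - single_rate,
        ],
    )
    windows, truth = [], []
    for i, category in enumerate(categories):
        seq, core_off, half_off = _plant_window(
            rng, category, length, gc, core, halfsite, max_dist
        )
        wid = f"{id_prefix}{i:04d}"
        windows.append((wid, seq))
        truth.append(
            {
                "intron_id": wid,
                "category": str(category),
                "core_offsets": core_off,
                "halfsite_offsets": half_off,
            }
        )
    return windows, truth


def sim_intron_genome(
    n_fg: int = 40,
    n_bg: int = 100,
    dual_rate_fg: float = 0.18,
    dual_rate_bg: float = 0.06,
    window: tuple[int, int] = (80, 1),
    gc: float = 0.4,
    core: MotifPattern = CORE_ACTAA,
    halfsite: MotifPattern = HALFSITE_YAAY,
    max_dist: int = 20,
    seed: int = 0,
) -> tuple[GenomeSequence, list[IntronRecord], dict]:
    """A synthetic genome of single-intron contigs with planted 3'ss motifs.

    Foreground introns (emulating those whose retention responds to the
    perturbation) carry dual-core windows at ``dual_rate_fg``; background
    introns at ``dual_rate_bg``. Each intron sits on its own contig with
    random exon flanks, on a random strand. The planted window occupies
    intron positions -from_up..-to_up, so extraction with the same bounds
    recovers exactly the generated sequence.
    """
    from_up, to_up = window
    length = from_up - to_up + 1
    rng = _rng(seed, _STREAM_INTRONS)

    sequences: dict[str, str] = {}
    introns: list[IntronRecord] = []
    truth_windows: list[dict] = []

    for group, n_introns, dual_rate in (
        ("foreground", n_fg, dual_rate_fg),
        ("background", n_bg, dual_rate_bg),
    ):
        prefix = "fg" if group == "foreground" else "bg"
        wins, wtruth = sim_motif_windows(
            n_introns,
            dual_rate=dual_rate,
            length=length,
            gc=gc,
            core=core,
            halfsite=halfsite,
            max_dist=max_dist,
            rng=rng,
            id_prefix=prefix,
        )
        for (wid, wseq), wt in zip(wins, wtruth):
            pad5 = int(rng.integers(5, 31))
            tail = _random_dna(rng, to_up - 1, gc)  # between window and 3'ss
            intron_sense = _random_dna(rng, pad5, gc) + wseq + tail
            flank5 = _random_dna(rng, 10, gc)
            flank3 = _random_dna(rng, 10, gc)
            contig_sense = flank5 + intron_sense + flank3
            strand = "+" if rng.random() < 0.5 else "-"
            start = len(flank5)
            end = start + len(intron_sense)
            if strand == "-":
                contig = _revcomp(contig_sense)
                start, end = len(contig_sense) - end, len(contig_sense) - start
            else:
                contig = contig_sense
            chrom = f"ctg_{wid}"
            sequences[chrom] = contig
            introns.append(IntronRecord(chrom, start, end, strand, wid, group=group))
            wt["group"] = group
            truth_windows.append(wt)

    truth = {
        "window": [int(from_up), int(to_up)],
        "core": core.pattern,
        "halfsite": halfsite.pattern,
        "max_dist": int(max_dist),
        "windows": truth_windows,
    }
    return GenomeSequence(sequences), introns, truth


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# count matrices


def sim_counts(
    n_genes: int = 300,
    n_planted: int = 20,
    delta_pu: float = 30.0,
    baseline_pu: float = 10.0,
    depth_mean: float = 500.0,
    dispersion: float = 0.05,
    n_reps: int = 3,
    libsize_cv: float = 0.2,
    n_intronless: int = 100,
    class_l2fc: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, dict]:
    """Negative-binomial counts with planted percent-unspliced shifts.

    Per gene, the total (unspliced + spliced) count is negative-binomial
    with variance mu + dispersion*mu^2, scaled by lognormal per-sample
    library factors; the unspliced share is a binomial split at the group's
    true percent unspliced. ``class_l2fc`` optionally shifts treatment
    means (log2 units) for abundance-shift tests: key ``intron_containing``
    scales the totals of unspliced/spliced gene pairs (their split is still
    governed by percent unspliced), key ``intronless`` scales the intronless
    transcripts.
    """
    if baseline_pu + delta_pu > 100:
        raise ValueError("baseline_pu + delta_pu must be <= 100")
    rng = _rng(seed, _STREAM_COUNTS)
    class_l2fc = class_l2fc or {}

    samples = [f"ctrl_{i+1}" for i in range(n_reps)] + [f"trt_{i+1}" for i in range(n_reps)]
    groups = {s: ("control" if s.startswith("ctrl") else "treatment") for s in samples}
    sigma = np.sqrt(np.log1p(libsize_cv**2))
    lib_factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(samples))

    def _nb(mu: float) -> int:
        if mu <= 0:
            return 0
        size = 1.0 / dispersion
        p = size / (size + mu)
        return int(rng.negative_binomial(size, p))

    planted = {f"g{i:04d}": delta_pu for i in range(n_planted)}
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    gene_means = depth_mean * rng.lognormal(mean=0.0, sigma=0.3, size=n_genes)

    tx_ids, tx_class, tx_gene = [], [], []
    counts = []
    for gid, gmean in zip(gene_ids, gene_means):
        pu_ctrl = baseline_pu
        pu_trt = baseline_pu + planted.get(gid, 0.0)
        u_row, s_row = [], []
        for s_idx, smp in enumerate(samples):
            mu = gmean * lib_factors[s_idx]
            if groups[smp] == "treatment" and "intron_containing" in class_l2fc:
                mu *= 2.0 ** class_l2fc["intron_containing"]
            total = _nb(mu)
            pu = pu_trt if groups[smp] == "treatment" else pu_ctrl
            u = int(rng.binomial(total, pu / 100.0)) if total > 0 else 0
            u_row.append(u)
            s_row.append(total - u)
        tx_ids += [f"{gid}_pre", f"{gid}_m"]
        tx_class += ["unspliced", "spliced"]
        tx_gene += [gid, gid]
        counts += [u_row, s_row]

    for i in range(n_intronless):
        tid = f"nl{i:04d}"
        gmean = depth_mean * rng.lognormal(mean=0.0, sigma=0.3)
        row = []
        for s_idx, smp in enumerate(samples):
            mu = gmean * lib_factors[s_idx]
            if groups[smp] == "treatment" and "intronless" in class_l2fc:
                mu *= 2.0 ** class_l2fc["intronless"]
            row.append(_nb(mu))
        tx_ids.append(tid)
        tx_class.append("intronless")
        tx_gene.append(tid)
        counts.append(row)

    counts_df = pd.DataFrame(counts, index=tx_ids, columns=samples, dtype=float)
    meta = pd.DataFrame({"tx_class": tx_class, "gene_id": tx_gene}, index=tx_ids)
    tpm = counts_df / counts_df.sum(axis=0) * 1e6
    cm = CountMatrix(counts=counts_df, meta=meta, sample_groups=groups, tpm=tpm)
    truth = {
        "planted_genes": {g: float(d) for g, d in planted.items()},
        "baseline_pu": float(baseline_pu),
        "delta_pu": float(delta_pu),
        "class_l2fc": {k: float(v) for k, v in class_l2fc.items()},
        "lib_factors": {s: float(f) for s, f in zip(samples, lib_factors)},
    }
    return cm, truth


# ---------------------------------------------------------------------------
# proteomics


def sim_proteomics(
    n_proteins: int = 120,
    n_eu2: int = 40,
    binder_sets: dict[str, set[str]] | None = None,
    binder_prob: float = 0.6,
    nsc_scale: float = 1.0,
    n_dia_planted: int = 24,
    dia_reps: int = 3,
    planted_l2fc: float = 1.5,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], dict]:
    """NSC table plus DIA log2 intensities with planted binders.

    Planted substrate binders get NSC above the aptamer background (positive
    background-corrected enrichment); non-binders sit strictly below it.
    DIA intensities are normal on the log2 scale around planted group means
    for a two-condition (WT vs dnDEL) comparison.

    Returns (nsc_table, dia_intensities, dia_groups, truth).
    """
    from .proteomics import SUBSTRATES

    rng = _rng(seed, _STREAM_PROTEOMICS)
    protein_ids = [f"P{i:04d}" for i in range(n_proteins)]
    eu2_ids = list(rng.choice(protein_ids, size=n_eu2, replace=False))
    eu2_set = set(eu2_ids)

    if binder_sets is None:
        binder_sets = {
            sub: {p for p in protein_ids if rng.random() < binder_prob}
            for sub in SUBSTRATES
        }
    else:
        unknown = {p for s in binder_sets.values() for p in s} - set(protein_ids)
        if unknown:
            raise ValueError(f"binder_sets reference unknown proteins: {sorted(unknown)[:5]}")

    rows = []
    for pid in protein_ids:
        ne = float(rng.uniform(2.0, 10.0) * nsc_scale)
        apt = float(rng.uniform(0.5, 3.0) * nsc_scale)
        row = {"protein_id": pid, "NE": ne, "APT": apt, "eu2_member": pid in eu2_set}
        for sub in SUBSTRATES:
            if pid in binder_sets[sub]:
                row[sub] = apt + float(rng.uniform(0.5, 5.0) * nsc_scale)
            else:
                row[sub] = apt * float(rng.uniform(0.0, 0.95))
        rows.append(row)
    nsc = pd.DataFrame(rows)[["protein_id", "NE", "WT", "upDEL", "dnDEL", "2xDEL", "APT", "eu2_member"]]

    included = {p for p in eu2_set if any(p in binder_sets[s] for s in SUBSTRATES)}
    sign_counts = {
        sub: {
            "n_pos": len(included & binder_sets[sub]),
            "n_neg": len(included - binder_sets[sub]),
        }
        for sub in SUBSTRATES
    }

    dia_planted = list(rng.choice(protein_ids, size=n_dia_planted, replace=False))
    dia_signs = rng.choice([-1.0, 1.0], size=n_dia_planted)
    dia_truth = {p: float(s * planted_l2fc) for p, s in zip(dia_planted, dia_signs)}
    cols_a = [f"WT_{i+1}" for i in range(dia_reps)]
    cols_b = [f"dnDEL_{i+1}" for i in range(dia_reps)]
    groups = {**{c: "WT" for c in cols_a}, **{c: "dnDEL" for c in cols_b}}
    base = rng.uniform(18.0, 24.0, n_proteins)
    data = {}
    for pid, b in zip(protein_ids, base):
        shift = dia_truth.get(pid, 0.0)
        a_vals = b + shift + rng.normal(0.0, noise_sd, dia_reps)
        b_vals = b + rng.normal(0.0, noise_sd, dia_reps)
        data[pid] = list(a_vals) + list(b_vals)
    dia = pd.DataFrame.from_dict(data, orient="index", columns=cols_a + cols_b)
    dia.index.name = "protein_id"

    truth = {
        "eu2": sorted(eu2_set),
        "binder_sets": {s: sorted(b) for s, b in binder_sets.items()},
        "included": sorted(included),
        "sign_counts": sign_counts,
        "dia_planted_l2fc": dia_truth,
    }
    return nsc, dia, groups, truth
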