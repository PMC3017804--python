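"""De novo ZOOPS motif discovery by expectation-maximization.

Zero-or-one occurrence per sequence: each sequence either carries one
motif site (probability gamma, uniform over placements) or none.  Repeats
are handled by the outer mask-and-rediscover loop.  The EM log-likelihood
is asserted non-decreasing on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import SequenceRecord

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(AA_ORDER)}


@dataclass
class Motif:
    motif_id: int
    width: int
    pwm: np.ndarray                      # (width, 20), rows sum to 1
    information_content: float           # bits
    sites: list[tuple[str, int]]         # (gene_id, 0-based offset)

    def __post_init__(self) -> None:
        sums = self.pwm.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("pwm columns must sum to 1")

    @property
    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in self.pwm.argmax(axis=1))


@dataclass
class MotifMap:
    occurrences: dict[str, list[tuple[int, int, float]]] = \
        field(default_factory=dict)      # gene -> [(motif_id, offset, score)]


class _ZoopsState:
    """One EM fit at a fixed width."""

    def __init__(self, encoded, masks, width, background, rng,
                 pseudocount: float = 0.25):
        self.encoded = encoded
        self.masks = masks
        self.w = width
        self.bg = background
        self.pc = pseudocount
        self.gamma = 0.5
        self.base = [float(np.log(background)[s].sum()) for s in encoded]
        usable = [i for i, s in enumerate(encoded)
                  if len(s) >= width and self._n_windows(i) > 0]
        if not usable:
            raise ValueError("no sequence admits a site at this width")
        # seed PWM from one concrete subsequence, softly peaked
        i = usable[rng.integers(0, len(usable))]
        valid = self._valid_windows(i)
        j = valid[rng.integers(0, len(valid))]
        sub = self.encoded[i][j:j + width]
        pwm = np.tile(background, (width, 1)) * 0.5
        pwm[np.arange(width), sub] += 0.5
        self.pwm = pwm / pwm.sum(axis=1, keepdims=True)

    def _valid_windows(self, i) -> np.ndarray:
        length = len(self.encoded[i])
        if length < self.w:
            return np.array([], dtype=int)
        bad = np.lib.stride_tricks.sliding_window_view(
            self.masks[i], self.w).any(axis=1)
        return np.nonzero(~bad)[0]

    def _n_windows(self, i) -> int:
        return len(self._valid_windows(i))

    def _window_llr(self, i) -> tuple[np.ndarray, np.ndarray]:
        """(valid window offsets, log p(window|pwm)/p(window|bg))."""
        valid = self._valid_windows(i)
        if len(valid) == 0:
            return valid, np.array([])
        seq = self.encoded[i]
        windows = np.lib.stride_tricks.sliding_window_view(seq, self.w)[valid]
        logratio = np.log(self.pwm) - np.log(self.bg)[None, :]
        llr = logratio[np.arange(self.w), windows].sum(axis=1)
        return valid, llr

    def iterate(self) -> float:
        """One E+M step; returns the (pre-step) log-likelihood."""
        n = len(self.encoded)
        counts = np.tile(self.bg * self.pc, (self.w, 1))
        q_total = 0.0
        loglik = 0.0
        new_gamma_num = 0.0
        for i in range(n):
            valid, llr = self._window_llr(i)
            base = float(sum(np.log(self.bg[c])
                             for c in self.encoded[i]))
            if len(valid) == 0:
                loglik += base
                continue
            m = len(valid)
            ratio = self.gamma / m * np.exp(np.clip(llr, -700, 700))
            denom = (1.0 - self.gamma) + ratio.sum()
            loglik += base + np.log(denom)
            z = ratio / denom
            q = float(z.sum())
            q_total += q
            new_gamma_num += q
            windows = np.lib.stride_tricks.sliding_window_view(
                self.encoded[i], self.w)[valid]
            for k in range(self.w):
                np.add.at(counts[k], windows[:, k], z)
        self.pwm = counts / counts.sum(axis=1, keepdims=True)
        self.gamma = min(max(new_gamma_num / n, 1e-6), 1.0 - 1e-6)
        return loglik

    def log_prior(self) -> float:
        """Dirichlet(1 + pc*bg) log prior of the current PWM; the M-step
        maximizes likelihood + this, so monotonicity holds for the sum."""
        return float((self.pc * self.bg[None, :]
                      * np.log(self.pwm)).sum())

    def loglik_only(self) -> float:
        total = 0.0
        for i in range(len(self.encoded)):
            valid, llr = self._window_llr(i)
            base = float(sum(np.log(self.bg[c]) for c in self.encoded[i]))
            if len(valid) == 0:
                total += base
                continue
            ratio = self.gamma / len(valid) * np.exp(np.clip(llr, -700, 700))
            total += base + np.log((1.0 - self.gamma) + ratio.sum())
        return total

    def information_content(self) -> float:
        return float((self.pwm
                      * np.log2(self.pwm / self.bg[None, :])).sum())

    def best_sites(self, min_q: float = 0.9) -> list[tuple[int, int, float]]:
        """(sequence index, offset, posterior q) for sequences with a
        probable site.  True sites sit at q ~ 1 (their likelihood ratio is
        astronomical), while background sequences fluctuate around
        q ~ gamma, so a high threshold costs no recall."""
        out = []
        for i in range(len(self.encoded)):
            valid, llr = self._window_llr(i)
            if len(valid) == 0:
                continue
            ratio = self.gamma / len(valid) * np.exp(np.clip(llr, -700, 700))
            denom = (1.0 - self.gamma) + ratio.sum()
            q = float(ratio.sum() / denom)
            if q > min_q:
                j = int(valid[np.argmax(llr)])
                out.append((i, j, q))
        return out


def _encode_all(proteins):
    return [np.array([_AA_INDEX[c] for c in p.residues], dtype=np.intp)
            for p in proteins]


def _background_freqs(encoded) -> np.ndarray:
    counts = np.ones(20)
    for seq in encoded:
        counts += np.bincount(seq, minlength=20)
    return counts / counts.sum()


def _candidate_widths(w_min: int, w_max: int) -> list[int]:
    widths = []
    w = w_min
    while w < w_max:
        widths.append(w)
        w *= 2
    widths.append(w_max)
    return sorted(set(widths))


def discover_motifs(proteins: list[SequenceRecord], max_motifs: int = 8,
                    w_min: int = 6, w_max: int = 50, n_starts: int = 5,
                    seed: int = 0, ic_floor: float = 2.0,
                    max_iter: int = 200, tol: float = 1e-4) -> list[Motif]:
    """Mask-and-repeat ZOOPS EM discovery.

    For each motif: seed candidates at several widths and starting
    subsequences, run EM to convergence (log-likelihood delta < tol or
    max_iter), keep the best fit by likelihood gain over background, mask
    its sites, repeat until max_motifs or the information content drops
    below ic_floor.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two sequences")
    if all(len(p.residues) < w_min for p in proteins):
        raise ValueError("all sequences shorter than the minimum width")
    encoded = _encode_all(proteins)
    bg = _background_freqs(encoded)
    masks = [np.zeros(len(s), dtype=bool) for s in encoded]
    rng = np.random.default_rng(seed)
    motifs: list[Motif] = []

    for motif_idx in range(max_motifs):
        best: _ZoopsState | None = None
        best_gain = -np.inf
        for width in _candidate_widths(w_min, w_max):
            if all(len(s) < width for s in encoded):
                continue
            for _ in range(n_starts):
                try:
                    state = _ZoopsState(encoded, masks, width, bg, rng)
                except ValueError:
                    continue
                prev = -np.inf
                for _ in range(max_iter):
                    prior = state.log_prior()
                    ll = state.iterate()
                    obj = ll + prior
                    assert obj >= prev - 1e-6, \
                        "EM objective (log-likelihood + log prior) decreased"
                    if obj - prev < tol and np.isfinite(prev):
                        break
                    prev = obj
                final = state.loglik_only()
                null = _null_loglik(encoded, masks, bg, width)
                gain = (final - null) / width   # favor dense motifs
                if gain > best_gain:
                    best_gain = gain
                    best = state
        if best is not None:
            _harden(best)
            # iterate shift refinement: a start far out of phase can need
            # several column shifts to walk onto the true register
            prev_ll = -np.inf
            for _ in range(4):
                best = _refine_shifts(best, encoded, masks, bg, rng)
                _harden(best)
                ll = best.loglik_only()
                if ll <= prev_ll + 1e-6:
                    break
                prev_ll = ll
        if best is None:
            break
        sites = best.best_sites()
        # acceptance: per-column information content.  A floor on total IC
        # cannot reject null fits: on i.i.d. background the per-sequence
        # max over windows lets EM assemble a fuzzy motif whose total IC
        # grows with width (~1.6 bits/column), while genuine conserved
        # motifs run well above 3 bits/column.
        if best.information_content() / best.w < ic_floor:
            break
        if not sites:
            break
        motif = Motif(
            motif_id=motif_idx + 1,
            width=best.w,
            pwm=best.pwm.copy(),
            information_content=best.information_content(),
            sites=[(proteins[i].id, j) for i, j, _ in sites],
        )
        motifs.append(motif)
        for i, j, _ in sites:
            masks[i][j:j + best.w] = True
    return motifs


def _harden(state: _ZoopsState, rounds: int = 3,
            min_llr_per_col: float = 1.0) -> None:
    """Sharpen a converged fit by re-estimating the PWM from strong hard
    site assignments.  Soft EM can settle in a fuzzy optimum whose diluted
    mismatch penalties let chance part-matches pass as sites; rebuilding
    the PWM from sites whose own log-likelihood ratio is high (true sites
    run ~3 nats/column, part-matches well under 1) collapses it onto the
    real signal and the part-matches fall away."""
    for _ in range(rounds):
        strong = []
        for i in range(len(state.encoded)):
            valid, llr = state._window_llr(i)
            if len(valid) == 0:
                continue
            j = int(np.argmax(llr))
            if llr[j] >= min_llr_per_col * state.w:
                strong.append((i, int(valid[j])))
        if len(strong) < 2:
            return
        counts = np.tile(state.bg * state.pc, (state.w, 1))
        for i, j in strong:
            counts[np.arange(state.w), state.encoded[i][j:j + state.w]] += 1
        state.pwm = counts / counts.sum(axis=1, keepdims=True)
        state.gamma = min(max(len(strong) / len(state.encoded), 1e-6),
                          1.0 - 1e-6)


def _refine_shifts(state: _ZoopsState, encoded, masks, bg, rng,
                   max_shift: int = 3) -> _ZoopsState:
    """EM converges readily to a phase-shifted optimum; re-seed from the
    current sites shifted by a few columns and keep the best fit."""
    sites = state.best_sites()
    if not sites:
        return state
    best_state, best_ll = state, state.loglik_only()
    w = state.w
    for delta in range(-max_shift, max_shift + 1):
        if delta == 0:
            continue
        counts = np.tile(bg * 0.5, (w, 1))
        used = 0
        for i, j, _ in sites:
            jj = j + delta
            if jj < 0 or jj + w > len(encoded[i]):
                continue
            counts[np.arange(w), encoded[i][jj:jj + w]] += 1.0
            used += 1
        if used < max(2, len(sites) // 2):
            continue
        candidate = _ZoopsState(encoded, masks, w, bg, rng)
        candidate.pwm = counts / counts.sum(axis=1, keepdims=True)
        candidate.gamma = state.gamma
        prev = -np.inf
        for _ in range(10):
            ll = candidate.iterate()
            if ll - prev < 1e-4 and np.isfinite(prev):
                break
            prev = ll
        _harden(candidate)
        ll = candidate.loglik_only()
        if ll > best_ll + 1e-9:
            best_state, best_ll = candidate, ll
    return best_state


def _null_loglik(encoded, masks, bg, width) -> float:
    total = 0.0
    for seq in encoded:
        total += float(sum(np.log(bg[c]) for c in seq))
    return total


def motif_llr_scores(motif: Motif, residues: str,
                     background: np.ndarray) -> np.ndarray:
    """Per-offset log2 likelihood ratio of one motif along a sequence."""
    seq = np.array([_AA_INDEX[c] for c in residues], dtype=np.intp)
    if len(seq) < motif.width:
        return np.array([])
    windows = np.lib.stride_tricks.sliding_window_view(seq, motif.width)
    logratio = np.log2(motif.pwm) - np.log2(background)[None, :]
    return logratio[np.arange(motif.width), windows].sum(axis=1)


def assign_motif_map(proteins: list[SequenceRecord], motifs: list[Motif],
                     score_threshold: float = 6.0) -> MotifMap:
    """Greedy best-scoring non-overlapping placements per gene."""
    encoded = _encode_all(proteins)
    bg = _background_freqs(encoded)
    out = MotifMap()
    for protein in proteins:
        candidates = []
        for motif in motifs:
            scores = motif_llr_scores(motif, protein.residues, bg)
            for offset, score in enumerate(scores):
                if score >= score_threshold:
                    candidates.append((float(score), motif.motif_id,
                                       offset, motif.width))
        chosen: list[tuple[int, int, float]] = []
        taken: list[tuple[int, int]] = []
        for score, motif_id, offset, width in sorted(
                candidates, key=lambda c: (-c[0], c[1], c[2])):
            span = (offset, offset + width)
            if any(span[0] < t_end and t_start < span[1]
                   for t_start, t_end in taken):
                continue
            taken.append(span)
            chosen.append((motif_id, offset, score))
        out.occurrences[protein.id] = sorted(chosen, key=lambda c: c[1])
    return out


def compare_motif_maps(map_a: list[tuple[int, int, float]],
                       map_b: list[tuple[int, int, float]]
                       ) -> tuple[float, bool]:
    """(multiset Jaccard of motif ids, ordered-sequence match flag)."""
    ids_a = [m for m, _, _ in map_a]
    ids_b = [m for m, _, _ in map_b]
    if not ids_a and not ids_b:
        return 1.0, True
    all_ids = set(ids_a) | set(ids_b)
    inter = sum(min(ids_a.count(i), ids_b.count(i)) for i in all_ids)
    union = sum(max(ids_a.count(i), ids_b.count(i)) for i in all_ids)
    return inter / union, ids_a == ids_b


def write_meme_minimal(motifs: list[Motif], background: np.ndarray,
                       path) -> None:
    lines = ["MEME version 4", "", "ALPHABET= " + AA_ORDER, "",
             "Background letter frequencies",
             " ".join(f"{aa} {f:.5f}"
                      for aa, f in zip(AA_ORDER, background)), ""]
    for motif in motifs:
        lines.append(f"MOTIF M{motif.motif_id} {motif.consensus}")
        lines.append(
            f"letter-probability matrix: alength= 20 w= {motif.width} "
            f"nsites= {len(motif.sites)} E= 0")
        for row in motif.pwm:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
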