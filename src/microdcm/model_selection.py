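"""Random-effects Bayesian model selection over models and families.

Per-subject log model evidences (variational free energies) feed a
variational Dirichlet update over population model frequencies; exceedance
probabilities — the probability that a model (or family) is the most
frequent in the population — are estimated by seeded Dirichlet sampling,
with a closed-form regularized-incomplete-Beta cross-check for two models.

Family-level comparison aggregates model evidence within each family with a
uniform within-family model prior (``logsumexp(F) - log K_family``) before
running the same Dirichlet scheme over families, so family size does not
bias the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import betainc, digamma, gammaln, logsumexp

__all__ = [
    "EvidenceTable",
    "BMSResult",
    "rfx_bms",
    "exceedance_probabilities",
    "exceedance_closed_form_2",
    "family_bms",
    "read_evidence_tsv",
    "write_evidence_tsv",
]


@dataclass
class EvidenceTable:
    """Per-subject log model evidences (free energies, nats)."""

    log_evidence: np.ndarray  # (n_subjects, n_models)
    model_ids: list
    subjects: list | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.log_evidence = np.atleast_2d(np.asarray(self.log_evidence, dtype=float))
        if self.log_evidence.shape[1] != len(self.model_ids):
            raise ValueError("log_evidence columns must match model_ids")
        if self.log_evidence.shape[1] < 2:
            raise ValueError("need at least 2 models for comparison")
        if not np.all(np.isfinite(self.log_evidence)):
            raise ValueError("log evidences must be finite")
        if self.subjects is not None and len(self.subjects) != self.log_evidence.shape[0]:
            raise ValueError("subjects must match log_evidence rows")

    @property
    def n_subjects(self) -> int:
        return self.log_evidence.shape[0]

    @property
    def n_models(self) -> int:
        return self.log_evidence.shape[1]

    def select(self, model_ids: Sequence) -> "EvidenceTable":
        cols = [self.model_ids.index(m) for m in model_ids]
        return EvidenceTable(
            self.log_evidence[:, cols], list(model_ids), self.subjects, self.group
        )


@dataclass
class BMSResult:
    """Dirichlet posterior over model (or family) frequencies."""

    alpha: np.ndarray
    expected_prob: np.ndarray
    exceedance_prob: np.ndarray
    level: str  # 'model' | 'family'
    labels: list
    protected_exceedance_prob: np.ndarray | None = None
    bor: float | None = None
    warning: str | None = None
    attributions: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "level": self.level,
            "labels": list(self.labels),
            "alpha": self.alpha.tolist(),
            "expected_prob": self.expected_prob.tolist(),
            "exceedance_prob": self.exceedance_prob.tolist(),
            "warning": self.warning,
        }
        if self.protected_exceedance_prob is not None:
            d["protected_exceedance_prob"] = self.protected_exceedance_prob.tolist()
            d["bor"] = self.bor
        return d


def _vb_dirichlet(L: np.ndarray, alpha0: np.ndarray, max_iter: int = 200,
                  tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Variational update of Dirichlet concentrations from log evidences."""
    N, K = L.shape
    alpha = alpha0.copy()
    u = np.full((N, K), 1.0 / K)
    for _ in range(max_iter):
        lw = L + digamma(alpha)[None, :] - digamma(alpha.sum())
        lw = lw - lw.max(axis=1, keepdims=True)
        u = np.exp(lw)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, u


def exceedance_closed_form_2(alpha1: float, alpha2: float) -> float:
    """P(r1 > r2) for r ~ Dirichlet(a1, a2): ``1 - I_0.5(a1, a2)``."""
    return float(1.0 - betainc(alpha1, alpha2, 0.5))


def exceedance_probabilities(
    alpha: np.ndarray,
    n_samples: int = 1_000_000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Exceedance probabilities by seeded Dirichlet sampling."""
    alpha = np.asarray(alpha, dtype=float)
    if not np.all(alpha > 0):
        raise ValueError("alpha must be positive")
    if n_samples < 1000:
        raise ValueError("n_samples < 1000 gives unusable precision")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    K = len(alpha)
    counts = np.zeros(K, dtype=np.int64)
    chunk = 200_000
    remaining = int(n_samples)
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(alpha, size=m)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=K)
        remaining -= m
    return counts / float(n_samples)


def _rfx_free_energy(L, alpha0, alpha, u) -> float:
    """Variational lower bound of the random-effects (H1) model."""
    Elogr = digamma(alpha) - digamma(alpha.sum())
    acc = float(np.sum(u * (L + Elogr[None, :])))
    ent_u = -float(np.sum(u * np.log(np.clip(u, 1e-300, None))))
    lnB = lambda a: float(np.sum(gammaln(a)) - gammaln(np.sum(a)))
    kl_dir = (
        lnB(alpha0)
        - lnB(alpha)
        + float((alpha - alpha0) @ Elogr)
    )
    return acc + ent_u - kl_dir


def _null_free_energy(L) -> float:
    """Evidence under the null: all models equally frequent for everyone."""
    K = L.shape[1]
    return float(np.sum(logsumexp(L, axis=1) - np.log(K)))


def rfx_bms(
    table: EvidenceTable,
    alpha0: np.ndarray | None = None,
    *,
    n_samples: int = 1_000_000,
    seed: int | np.random.Generator = 0,
    compute_protected: bool = False,
    level: str = "model",
    labels: list | None = None,
) -> BMSResult:
    """Random-effects BMS from per-subject log evidences.

    Uniform Dirichlet prior (alpha0 = 1 per model) unless overridden.
    Adding any per-subject constant to a row of the evidence table leaves
    the result unchanged.
    """
    L = table.log_evidence
    N, K = L.shape
    alpha0 = np.ones(K) if alpha0 is None else np.asarray(alpha0, dtype=float)
    if alpha0.shape != (K,) or not np.all(alpha0 > 0):
        raise ValueError("alpha0 must be positive with one entry per model")

    warning = None
    row_ranges = L.max(axis=1) - L.min(axis=1)
    if N == 1 and np.all(row_ranges < 1e-12):
        warning = "single subject with tied evidences; returning uniform result"
        alpha = alpha0 + 1.0 / K
        u = np.full((N, K), 1.0 / K)
    else:
        alpha, u = _vb_dirichlet(L, alpha0)

    expected = alpha / alpha.sum()
    xp = exceedance_probabilities(alpha, n_samples=n_samples, seed=seed)

    pxp = None
    bor = None
    if compute_protected:
        F1 = _rfx_free_energy(L, alpha0, alpha, u)
        F0 = _null_free_energy(L)
        bor = float(1.0 / (1.0 + np.exp(F1 - F0)))
        pxp = xp * (1.0 - bor) + bor / K

    return BMSResult(
        alpha=alpha,
        expected_prob=expected,
        exceedance_prob=xp,
        level=level,
        labels=list(labels) if labels is not None else list(table.model_ids),
        protected_exceedance_prob=pxp,
        bor=bor,
        warning=warning,
        attributions=u,
    )


def family_bms(
    table: EvidenceTable,
    partition: Mapping[int, Sequence],
    *,
    n_samples: int = 1_000_000,
    seed: int | np.random.Generator = 0,
    compute_protected: bool = False,
) -> BMSResult:
    """Family-level random-effects BMS.

    ``partition`` maps family id -> model ids.  Each family's per-subject
    evidence is the log mean evidence of its members (uniform within-family
    model prior), which neutralizes family size: with all-equal evidences a
    1-model family and a 2-model family tie at exceedance 0.5.  Singleton
    partitions reduce exactly to :func:`rfx_bms`.
    """
    fam_ids = sorted(partition)
    covered: list = []
    for fam in fam_ids:
        members = list(partition[fam])
        if not members:
            raise ValueError(f"family {fam} is empty")
        covered += members
    if sorted(covered, key=str) != sorted(table.model_ids, key=str):
        raise ValueError(
            "partition must cover the evidence table's models exactly: "
            f"{covered} vs {table.model_ids}"
        )

    cols = {m: j for j, m in enumerate(table.model_ids)}
    L_fam = np.empty((table.n_subjects, len(fam_ids)))
    for fi, fam in enumerate(fam_ids):
        members = [cols[m] for m in partition[fam]]
        L_fam[:, fi] = logsumexp(table.log_evidence[:, members], axis=1) - np.log(
            len(members)
        )

    fam_table = EvidenceTable(
        L_fam, model_ids=list(fam_ids), subjects=table.subjects, group=table.group
    )
    return rfx_bms(
        fam_table,
        n_samples=n_samples,
        seed=seed,
        compute_protected=compute_protected,
        level="family",
        labels=list(fam_ids),
    )


def write_evidence_tsv(path, table: EvidenceTable) -> None:
    subjects = table.subjects or [f"sub-{i + 1:02d}" for i in range(table.n_subjects)]
    with open(path, "w") as fh:
        fh.write("subject\t" + "\t".join(str(m) for m in table.model_ids) + "\n")
        for s, row in zip(subjects, table.log_evidence):
            fh.write(str(s) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_evidence_tsv(path, group: str | None = None) -> EvidenceTable:
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[0] != "subject":
            raise ValueError(f"{path}: expected 'subject' as first column")
        model_ids: list = []
        for tok in header[1:]:
            try:
                model_ids.append(int(tok))
            except ValueError:
                model_ids.append(tok)
        subjects = []
        rows = []
        for line in fh:
            parts = line.strip().split("\t")
            if not parts or parts == [""]:
                continue
            subjects.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return EvidenceTable(np.array(rows), model_ids, subjects, group)
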