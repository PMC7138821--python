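"""Subpopulation membership calls and representative-accession selection.

Membership uses the 0.65 rule set: a sample whose largest admixture
component reaches 0.65 belongs to that subpopulation; otherwise, if the
summed components of the subpopulations within a single major variety group
(cA, XI or GJ) reach 0.65 the sample is admixed within that group
("cA-adm", "XI-adm", "GJ-adm"); all remaining samples are fully admixed.

Representatives are chosen per group as the entry nearest (in the first
five principal-coordinate axes of the identity-by-state distance matrix)
to the group centroid, among entries for which seed is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import MISSING, GenotypeMatrix, QMatrix, ValidationError

MAJOR_GROUP_ORDER = ("cA", "XI", "GJ")


@dataclass
class GroupScheme:
    """Column names of a Q matrix and their major-group assignment."""

    group_names: list[str]
    major_group_map: dict[str, str]

    def __post_init__(self) -> None:
        for g in self.group_names:
            mg = self.major_group_map.get(g)
            if mg is None:
                raise ValidationError(f"group {g!r} has no major-group assignment")
            if mg not in MAJOR_GROUP_ORDER + ("other",):
                raise ValidationError(f"unknown major group {mg!r} for {g!r}")

    def majors(self) -> np.ndarray:
        return np.array([self.major_group_map[g] for g in self.group_names])


@dataclass
class MembershipCall:
    sample_id: str
    label: str
    max_component: float
    major_sums: dict[str, float]


def classify(q_row: np.ndarray, scheme: GroupScheme, threshold: float = 0.65,
             sample_id: str = "") -> MembershipCall:
    """Apply the membership rules to one row of admixture proportions."""
    q = np.asarray(q_row, dtype=float)
    if len(q) != len(scheme.group_names):
        raise ValidationError("q_row length does not match scheme")
    if abs(q.sum() - 1.0) > 1e-6:
        raise ValidationError("q_row must lie on the simplex")
    majors = scheme.majors()
    sums = {mg: float(q[majors == mg].sum()) for mg in MAJOR_GROUP_ORDER}
    top = int(np.argmax(q))
    thr = threshold - 1e-9  # ">= threshold" robust to float representation
    if threshold > 0.5:
        assert (q >= thr).sum() <= 1, "multiple components above a >0.5 threshold"
    if q[top] >= thr:
        label = scheme.group_names[top]
    else:
        # fixed evaluation order cA, XI, GJ; maximal sum wins ties
        best = max(MAJOR_GROUP_ORDER, key=lambda mg: sums[mg])
        label = f"{best}-adm" if sums[best] >= thr else "admixed"
    return MembershipCall(sample_id, label, float(q[top]), sums)


def classify_all(q: QMatrix, scheme: GroupScheme, threshold: float = 0.65) -> list[MembershipCall]:
    return [classify(row, scheme, threshold, sid)
            for sid, row in zip(q.sample_ids, q.proportions)]


def ibs_distance(G: GenotypeMatrix) -> np.ndarray:
    """Identity-by-state distance over pairwise-complete SNPs.

    d_ij = 1 - mean over shared SNPs of (2 - |g_i - g_j|) / 2, i.e. half the
    mean absolute dosage difference.
    """
    g = G.dosages.astype(float)
    obs = G.dosages != MISSING
    n = G.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        both = obs[i] & obs[i + 1:]
        m_ij = both.sum(axis=1)
        zero = np.nonzero(m_ij == 0)[0]
        if len(zero):
            j = i + 1 + int(zero[0])
            raise ValidationError(
                f"samples {G.sample_ids[i]!r} and {G.sample_ids[j]!r} share no SNPs"
            )
        diff = np.abs(g[i] - g[i + 1:]) * both
        d[i, i + 1:] = d[i + 1:, i] = diff.sum(axis=1) / (2.0 * m_ij)
    return d


def principal_axes(D: np.ndarray, n_axes: int = 5) -> np.ndarray:
    """Principal coordinates (classical MDS) of a distance matrix.

    Double-centers -D^2/2, takes the top eigenvectors scaled by the square
    root of their eigenvalues, and fixes each axis's sign so its
    largest-magnitude loading is positive.  If fewer than *n_axes* positive
    eigenvalues exist the available axes are returned with a warning.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 1.0) * 1e-12
    k = int(pos.sum())
    if k < n_axes:
        import warnings
        warnings.warn(f"only {k} positive eigenvalues; returning {k} axes", RuntimeWarning)
    k = min(k, n_axes)
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    for a in range(k):
        if coords[np.argmax(np.abs(coords[:, a])), a] < 0:
            coords[:, a] = -coords[:, a]
    return coords


def select_representative(coords: np.ndarray, calls: list[MembershipCall],
                          target_group: str, available: dict[str, bool]) -> str:
    """Group member nearest the group centroid among available entries.

    The centroid is the mean coordinate over all members of the group; only
    entries flagged available can be returned.  Ties break lexicographically
    by sample id.
    """
    idx = [i for i, c in enumerate(calls) if c.label == target_group]
    if not idx:
        raise ValidationError(f"no samples classified as {target_group!r}")
    centroid = coords[idx].mean(axis=0)
    candidates = [i for i in idx if available.get(calls[i].sample_id, False)]
    if not candidates:
        raise ValidationError(f"no available member of group {target_group!r}")
    dists = np.linalg.norm(coords[candidates] - centroid, axis=1)
    best = min(zip(dists, (calls[i].sample_id for i in candidates)),
               key=lambda t: (t[0], t[1]))
    return best[1]
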