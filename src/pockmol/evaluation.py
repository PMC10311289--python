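"""Evaluation metrics for generated molecule sets.

Validity, RDKit drug-likeness descriptors (QED, SA, logP, TPSA, MW),
Tanimoto-based diversity, high-affinity ratio against a reference docking
score, and compliance fractions against requested property thresholds.
Docking itself is never re-implemented: an :class:`AffinityScorer` seam
wraps an external binary or a deterministic mock.
"""

from __future__ import annotations

import hashlib
import shutil
import sys
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, QED, RDConfig, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs

sys.path.append(RDConfig.RDContribDir + "/SA_Score")
import sascorer  # noqa: E402  (ships with RDKit's contrib tree)

RDLogger.DisableLog("rdApp.*")


@dataclass(frozen=True)
class MolProperties:
    qed: float
    sa: float
    logp: float
    tpsa: float
    mw: float

    def as_dict(self) -> dict[str, float]:
        return {"QED": self.qed, "SA": self.sa, "logP": self.logp,
                "TPSA": self.tpsa, "MW": self.mw}


def mol_properties(smiles: str) -> MolProperties | None:
    """Standard RDKit descriptors; None flags an unparseable SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return MolProperties(
        qed=float(QED.qed(mol)),
        sa=float(sascorer.calculateScore(mol)),
        logp=float(Crippen.MolLogP(mol)),
        tpsa=float(rdMolDescriptors.CalcTPSA(mol)),
        mw=float(Descriptors.MolWt(mol)),
    )


def diversity(smiles_list: list[str], radius: int = 2,
              n_bits: int = 2048) -> float | None:
    """1 - (1/N^2) * sum of pairwise Tanimoto over all ordered pairs.

    Self-pairs are included, exactly as the 1/N^2 normalization implies, so
    a set of identical molecules scores 0. Returns None on an empty set.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        fps.append(gen.GetFingerprint(mol))
    n = len(fps)
    if n == 0:
        return None
    total = 0.0
    for i in range(n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps)
        total += float(np.sum(sims))
    return 1.0 - total / n**2


def high_affinity_ratio(generated_scores: list[float], reference_score: float,
                        better_is_lower: bool = True) -> float | None:
    """Percentage of scores at least as good as the reference.

    Docking scores are kcal/mol with negative = better, so "at least as
    good" means score <= reference; set better_is_lower=False to flip.
    """
    scores = np.asarray(generated_scores, dtype=float)
    if scores.size == 0:
        return None
    if better_is_lower:
        ok = scores <= reference_score
    else:
        ok = scores >= reference_score
    return 100.0 * float(ok.mean())


def compliance(per_molecule: list[dict[str, float]],
               requested: dict[str, tuple[str, float]]) -> dict[str, float]:
    """Fraction of molecules meeting each requested (direction, threshold).

    Directions are "le"/"ge" with inclusive boundaries, matching the hard
    property binarization rules.
    """
    out: dict[str, float] = {}
    for name, (direction, threshold) in requested.items():
        if direction not in ("le", "ge"):
            raise ValueError("direction must be 'le' or 'ge'")
        values = np.array([p[name] for p in per_molecule], dtype=float)
        if values.size == 0:
            out[name] = float("nan")
            continue
        ok = values <= threshold if direction == "le" else values >= threshold
        out[name] = float(ok.mean())
    return out


# ---------------------------------------------------------------------------
# Affinity scorer seam
# ---------------------------------------------------------------------------

class ScorerUnavailable(RuntimeError):
    pass


@runtime_checkable
class AffinityScorer(Protocol):
    def score(self, pocket, smiles: str) -> float: ...


class MockAffinityScorer:
    """Deterministic pseudo docking: -5 - 3*(contains N) + small hash noise.

    Mirrors the fixture corpus score rule so conditioning experiments close
    the loop without an external docking binary.
    """

    def score(self, pocket, smiles: str) -> float:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"cannot score invalid SMILES {smiles!r}")
        has_n = any(a.GetSymbol() == "N" for a in mol.GetAtoms())
        digest = hashlib.sha256(smiles.encode()).digest()
        noise = (int.from_bytes(digest[:8], "big") / 2**64 - 0.5) * 0.4
        return -5.0 - 3.0 * float(has_n) + noise


class ExternalDockingScorer:
    """Subprocess wrapper around an external docking binary (e.g. vina).

    Declared unavailable when the binary is not on PATH; scoring protocol
    (receptor/ligand preparation) must be supplied by the caller via a
    prepared command template.
    """

    def __init__(self, binary: str = "vina"):
        self.binary = binary
        if shutil.which(binary) is None:
            raise ScorerUnavailable(f"docking binary {binary!r} not found on PATH")

    def score(self, pocket, smiles: str) -> float:  # pragma: no cover
        raise NotImplementedError(
            "external docking requires prepared receptor/ligand files; "
            "integrate via a custom AffinityScorer"
        )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    n_generated: int
    n_valid: int
    validity_rate: float
    diversity: float | None
    property_means: dict[str, float]
    property_sds: dict[str, float]
    har: float | None
    compliance: dict[str, float]
    notes: list[str] = field(default_factory=list)


def evaluate(generated_smiles: list[str],
             reference_score: float | None = None,
             scorer: AffinityScorer | None = None,
             pocket=None,
             requested: dict[str, tuple[str, float]] | None = None
             ) -> MetricsReport:
    """Validity filter -> descriptors -> diversity -> compliance -> HAR."""
    if len(generated_smiles) == 0:
        raise ValueError("generated set is empty")
    valid_smiles, props = [], []
    for s in generated_smiles:
        p = mol_properties(s)
        if p is not None:
            valid_smiles.append(s)
            props.append(p)
    n, n_valid = len(generated_smiles), len(valid_smiles)
    report = MetricsReport(
        n_generated=n,
        n_valid=n_valid,
        validity_rate=n_valid / n,
        diversity=None,
        property_means={},
        property_sds={},
        har=None,
        compliance={},
    )
    if n_valid == 0:
        report.notes.append("no valid molecules; metrics omitted")
        return report
    report.diversity = diversity(valid_smiles)
    table = [p.as_dict() for p in props]
    for key in table[0]:
        vals = np.array([row[key] for row in table])
        report.property_means[key] = float(vals.mean())
        report.property_sds[key] = float(vals.std(ddof=0))
    if requested:
        report.compliance = compliance(table, requested)
    if scorer is not None and reference_score is not None:
        scores = [scorer.score(pocket, s) for s in valid_smiles]
        report.har = high_affinity_ratio(scores, reference_score)
    elif reference_score is not None:
        report.notes.append("no scorer available; HAR omitted")
    return report


def report_to_tsv(report: MetricsReport) -> str:
    cols = {
        "n_generated": report.n_generated,
        "n_valid": report.n_valid,
        "validity_rate": f"{report.validity_rate:.4f}",
        "diversity": "" if report.diversity is None else f"{report.diversity:.4f}",
        "har": "" if report.har is None else f"{report.har:.2f}",
    }
    for key, val in report.property_means.items():
        cols[f"mean_{key}"] = f"{val:.4f}"
        cols[f"sd_{key}"] = f"{report.property_sds[key]:.4f}"
    for key, val in report.compliance.items():
        cols[f"compliance_{key}"] = f"{val:.4f}"
    header = "\t".join(cols)
    row = "\t".join(str(v) for v in cols.values())
    return header + "\n" + row + "\n"


def per_molecule_tsv(smiles_list: list[str],
                     scorer: AffinityScorer | None = None,
                     pocket=None) -> str:
    lines = ["smiles\tvalid\tQED\tSA\tlogP\tTPSA\tMW\tscore"]
    for s in smiles_list:
        p = mol_properties(s)
        if p is None:
            lines.append(f"{s}\t0\t\t\t\t\t\t")
            continue
        score = ""
        if scorer is not None:
            score = f"{scorer.score(pocket, s):.3f}"
        lines.append(
            f"{s}\t1\t{p.qed:.4f}\t{p.sa:.4f}\t{p.logp:.4f}\t"
            f"{p.tpsa:.4f}\t{p.mw:.3f}\t{score}"
        )
    return "\n".join(lines) + "\n"
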