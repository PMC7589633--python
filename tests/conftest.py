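import numpy as np
import pandas as pd
import pytest

from fflnet import expr, fflcore, synthdata
from fflnet.netio import Regulation, build_network


@pytest.fixture
def toy_network():
    """9 distinct typed edges: 3 tf_gene + 2 tf_mirna + 4 mirna_gene."""
    regs = [
        Regulation("T1", "G1", "tf_gene"),
        Regulation("T1", "G2", "tf_gene"),
        Regulation("T2", "G3", "tf_gene"),
        Regulation("T1", "m1", "tf_mirna"),
        Regulation("T2", "m2", "tf_mirna"),
        Regulation("m1", "G1", "mirna_gene"),
        Regulation("m1", "G2", "mirna_gene"),
        Regulation("m2", "G3", "mirna_gene"),
        Regulation("m2", "G4", "mirna_gene"),
    ]
    return build_network(regs)


def paired_study(matrix: np.ndarray, n_mirna_rows: int = 0, prefix: str = "F") -> expr.ExpressionStudy:
    """Wrap a (features x 2*n_pairs) array into a case/control paired study."""
    n_feat, n_samp = matrix.shape
    assert n_samp % 2 == 0
    n_pairs = n_samp // 2
    donors = [f"D{i}" for i in range(n_pairs)]
    cols = [f"{d}_case" for d in donors] + [f"{d}_control" for d in donors]
    frame = pd.DataFrame(matrix, index=[f"{prefix}{i}" for i in range(n_feat)], columns=cols)
    samples = pd.DataFrame(
        {"condition": ["case"] * n_pairs + ["control"] * n_pairs, "pair_id": donors * 2},
        index=pd.Index(cols, name="sample"),
    )
    split = n_feat - n_mirna_rows
    genes = frame.iloc[:split]
    mirnas = frame.iloc[split:].rename(index=lambda s: "m" + s)
    if n_mirna_rows == 0:
        # every study needs a miRNA matrix; reuse one row under a distinct id
        mirnas = frame.iloc[:1].rename(index=lambda s: "m" + s)
        genes = frame
    return expr.ExpressionStudy(genes=genes, mirnas=mirnas, samples=samples)


@pytest.fixture(scope="session")
def planted_run():
    """One seeded synthetic run scored end-to-end; shared by read-only tests."""
    net, truth = synthdata.synth_network(seed=1)
    study, truth = synthdata.synth_expression(net, truth, seed=101)
    de = {
        "gene": expr.moderated_de(study, "gene"),
        "miRNA": expr.moderated_de(study, "miRNA"),
    }
    scorer = fflcore.TripleScorer(study, de)
    ffls = fflcore.enumerate_ffls(net)
    scored = fflcore.score_ffls(ffls, study, de, scorer=scorer)
    null = fflcore.permutation_null(net, study, de, n_draws=5000, seed=201, scorer=scorer)
    flagged = fflcore.flag_dysregulated(scored, null)
    return {
        "network": net,
        "truth": truth,
        "study": study,
        "de": de,
        "scorer": scorer,
        "flagged": flagged,
        "null": null,
    }
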