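import numpy as np
import pytest
from hypothesis import settings

from mrlink import SimPanelConfig, generate_two_sample_panel
from mrlink.summary_data import HarmonizedPanel, PanelRecord, VariantAssociation

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_panel(gamma, Gamma, sigma_x=None, sigma_y=None, rsids=None):
    """Construct a harmonized panel directly from arrays (test helper)."""
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    k = gamma.size
    sigma_x = np.full(k, 0.01) if sigma_x is None else np.asarray(sigma_x, float)
    sigma_y = np.full(k, 0.01) if sigma_y is None else np.asarray(sigma_y, float)
    rsids = rsids or [f"rs{j + 1}" for j in range(k)]
    recs = [
        PanelRecord(rsids[j], "A", "G", float(gamma[j]), float(sigma_x[j]),
                    float(Gamma[j]), float(sigma_y[j]), 0.25)
        for j in range(k)
    ]
    return HarmonizedPanel("X", "Y", recs)


@pytest.fixture
def simple_panel():
    return make_panel([0.1, 0.2, 0.3], [0.03, 0.05, 0.08])


@pytest.fixture
def sim_panel():
    panel, truth = generate_two_sample_panel(SimPanelConfig(seed=42))
    return panel, truth


def write_table(path, rows, columns=("SNP", "effect_allele", "other_allele",
                                     "eaf", "beta", "se", "pval", "n"),
                sep="\t"):
    """Write a delimited summary-statistics table for loader tests."""
    lines = [sep.join(columns)]
    for row in rows:
        lines.append(sep.join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def assoc(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.01, eaf=0.25, **kw):
    return VariantAssociation(rsid, ea, oa, beta, se, eaf=eaf, **kw)
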