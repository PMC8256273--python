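import numpy as np
import pytest

from feralscan import synthetic_data as sd


@pytest.fixture(scope="session")
def joint_fixture(tmp_path_factory):
    """Full synthetic bundle with 12 planted joint-signal genes."""
    out = tmp_path_factory.mktemp("joint")
    return sd.simulate_joint_fixture(out, seed=5)


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    """Random 20-gene annotated toy genome, written to disk."""
    seqs, genes = sd.simulate_annotated_genome(n_genes=20, seed=3)
    out = tmp_path_factory.mktemp("genome")
    fasta, gff = out / "genome.fa", out / "genes.gff3"
    sd.write_genome(seqs, genes, fasta, gff)
    return {"seqs": seqs, "genes": genes, "fasta": fasta, "gff": gff, "dir": out}


@pytest.fixture()
def small_panel():
    """Small five-panel genotype matrix with three planted loci."""
    model = sd.PopulationModel(n_sites=400, n_samples=15, seed=21)
    signal = sd.PlantedSignal(site_ids=(5, 100, 399), focal_freq=1.0,
                              ref_freq_max=0.1, standing_freq_wild=0.0,
                              standing_freq_cultivated=0.0)
    freqs, truth = sd.simulate_panel_frequencies(model, signal)
    gm = sd.sample_genotypes(freqs, model)
    return {"model": model, "signal": signal, "freqs": freqs,
            "truth": truth, "gm": gm}


def brute_force_frequencies(gm, population):
    """Independent per-site allele count from raw dosages."""
    idx = [i for i, s in enumerate(gm.samples) if gm.pop_map[s] == population]
    p, n = [], []
    for j in range(gm.n_sites):
        col = [gm.calls[i, j] for i in idx]
        called = [c for c in col if c >= 0]
        n.append(len(called))
        p.append(sum(called) / (2 * len(called)) if called else np.nan)
    return np.array(p), np.array(n)
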