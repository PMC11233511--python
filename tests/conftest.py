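"""Shared fixtures.

The expensive artifacts — a motif-rich synthetic genome, a tiny pre-trained
language model, a planted-motif classification task, and an IA3 fine-tuned
classifier — are built once per session and shared across the end-to-end,
interpretability and variant-scoring tests.
"""

import numpy as np
import pytest

import plantlm as plm
from plantlm.pretrain import ScheduleConfig, chunk_genome, pretrain
from plantlm.synth import SyntheticGenomeSpec, generate_genome, generate_motif_task

# desk-scale study conditions (see docs/methods.md)
PRETRAIN_MOTIF = "TGACGTCATCGATCGTACGGATCCTAGCAATGCTTG"  # 36 bp
PRETRAIN_STEPS = 500
PRETRAIN_SEED = 1


@pytest.fixture(scope="session")
def vocab():
    return plm.build_vocab()


@pytest.fixture(scope="session")
def tiny_vocab():
    """1-mer vocabulary over {A,C,G,T}: 13 tokens, fast models."""
    return plm.build_vocab(kmer_size=1)


@pytest.fixture(scope="session")
def motif_genome():
    """200-kb motif-rich genome: 4 chromosomes x 50 kb tiled with a 36-bp
    consensus separated by 2-8 bp random spacers."""
    spec = SyntheticGenomeSpec(n_chromosomes=4, chromosome_length=50_000,
                               motif=PRETRAIN_MOTIF, motif_layout="tiled",
                               seed=11)
    return generate_genome(spec)


@pytest.fixture(scope="session")
def pretrained_tiny(motif_genome, vocab):
    """Tiny model (2 layers, dim 64) pre-trained for 500 steps on the
    motif-rich genome; returns (model, loss trace)."""
    chunks = list(chunk_genome(motif_genome.chromosomes, chunk_length=350, overlap=50))
    model = plm.build_model(plm.make_config("tiny"), seed=0)
    cfg = ScheduleConfig(warmup_steps=50, init_lr=6e-4, peak_lr=6e-3, total_steps=501)
    trace = pretrain(model, chunks, vocab, cfg, steps=PRETRAIN_STEPS,
                     seed=PRETRAIN_SEED, batch_size=24)
    return model, trace


@pytest.fixture(scope="session")
def motif_task():
    """Planted-motif binary classification task: 200-bp windows, 500/500."""
    return generate_motif_task(None, n_pos=500, n_neg=500, window=200, seed=7)


@pytest.fixture(scope="session")
def motif_task_dataset(motif_task, vocab):
    examples = [plm.SupervisedExample(
        id=e.id, tokens=plm.encode_for_model(e.sequence, vocab, 64),
        target=float(e.label), split=e.split) for e in motif_task.examples]
    return plm.SupervisedDataset(examples)


@pytest.fixture(scope="session")
def finetuned_classifier(pretrained_tiny, motif_task_dataset):
    """IA3 fine-tuned copy of the pre-trained tiny model on the planted task."""
    import copy
    model, _ = pretrained_tiny
    model = copy.deepcopy(model)
    backbone_before = {n: v.copy() for n, v in model.params.items()}
    task = plm.TaskHeadSpec("binary_classification", pooling="detection")
    metrics = plm.finetune(model, motif_task_dataset, task, epochs=40, seed=3,
                           lr=3e-2, batch_size=32)
    return model, metrics, backbone_before
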