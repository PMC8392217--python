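"""Protein sequence tokenization, embedding and 1-D convolution.

The global protein pathway represents each protein by its amino-acid
sequence, fixed to 1000 positions: shorter sequences are zero-padded, longer
ones truncated.  Tokens index a 21-symbol vocabulary (padding = 0, the 20
standard amino acids = 1..20) and are embedded into 128-dimensional vectors,
giving a 128 x 1000 feature matrix.  Three convolution blocks (valid 1-D
cross-correlation, LeakyReLU, max pooling) then produce the global feature
vector; the first block uses kernel size 5 with 64 filters, and all block
geometries are configurable.

This module holds the data-level operations (tokenize / embed / conv1d);
the trainable pathway lives in :mod:`cpinet.network`.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: token index per residue letter; 0 is reserved for padding.
AA_TO_TOKEN = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
PAD_TOKEN = 0
VOCAB_SIZE = len(AMINO_ACIDS) + 1  # 21
MAX_LEN = 1000
EMBED_DIM = 128


def tokenize(sequence: str, max_len: int = MAX_LEN) -> np.ndarray:
    """Map a sequence to a length-``max_len`` integer vector.

    Residues beyond ``max_len`` are cut; shorter sequences are suffix-padded
    with 0.  Letters outside the 20-residue alphabet (e.g. B, J, O, U, X, Z)
    map to the padding index with a logged warning.
    """
    tokens = np.zeros(max_len, dtype=np.int64)
    unknown = set()
    for i, aa in enumerate(sequence[:max_len].upper()):
        tok = AA_TO_TOKEN.get(aa)
        if tok is None:
            unknown.add(aa)
            tok = PAD_TOKEN
        tokens[i] = tok
    if unknown:
        logger.warning("unknown residue letters %s mapped to padding", sorted(unknown))
    return tokens


def embed(tokens: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Look tokens up in an embedding ``table`` of shape (vocab, dim).

    Returns the (dim, len) feature matrix whose column i is the embedding of
    token i.
    """
    tokens = np.asarray(tokens)
    table = np.asarray(table)
    if tokens.min() < 0 or tokens.max() >= table.shape[0]:
        raise ValueError("token index outside embedding table")
    return table[tokens].T


def conv1d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid 1-D cross-correlation: out[f, k] = sum_{c,j} x[c, k+j] w[f, c, j] + b[f].

    ``x`` has shape (channels, length), ``weight`` (filters, channels,
    kernel), ``bias`` (filters,).  Raises ``ValueError`` when the input is
    shorter than the kernel.  This is the pre-activation map; LeakyReLU and
    pooling are applied by the network blocks.
    """
    x = np.asarray(x, dtype=float)
    weight = np.asarray(weight, dtype=float)
    C, L = x.shape
    F, Cw, K = weight.shape
    if Cw != C:
        raise ValueError(f"weight expects {Cw} channels, input has {C}")
    if L < K:
        raise ValueError(f"input length {L} shorter than kernel size {K}")
    cols = np.lib.stride_tricks.sliding_window_view(x, K, axis=1)  # C,Lo,K
    out = np.einsum("clk,fck->fl", cols, weight) + np.asarray(bias, dtype=float)[:, None]
    return out


def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA; record id -> sequence string."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
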