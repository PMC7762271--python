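"""Regenerate the bundled synthetic domain-alignment and reference fixtures.

The shipped AP2/B3 alignments are synthetic: a seeded random consensus with
10 sequences mutated at ~10% of columns each, giving a strongly conserved
profile whose statistics (not whose letters) mimic a real domain seed
alignment.  The ERF-clade reference FASTA is derived from the AP2 profile
via genefamkit.subfamilies so that classifier and generator stay in sync.

Usage:  python scripts/make_profile_fixtures.py
"""

from __future__ import annotations

import pathlib

import numpy as np

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "genefamkit" / "data"
AA = "ACDEFGHIKLMNPQRSTVWY"


def make_alignment(length: int, n_seqs: int, conservation: float, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 20, size=length)
    seqs = []
    for _ in range(n_seqs):
        residues = consensus.copy()
        mutate = rng.random(length) >= conservation
        residues[mutate] = rng.integers(0, 20, size=int(mutate.sum()))
        seqs.append("".join(AA[i] for i in residues))
    return seqs


def write_fasta(path: pathlib.Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    ap2 = make_alignment(length=58, n_seqs=10, conservation=0.9, seed=7001)
    b3 = make_alignment(length=80, n_seqs=10, conservation=0.9, seed=7002)
    write_fasta(
        DATA / "ap2_domain_synthetic_alignment.fasta",
        [(f"AP2_synth_{i+1:02d}", s) for i, s in enumerate(ap2)],
    )
    write_fasta(
        DATA / "b3_domain_synthetic_alignment.fasta",
        [(f"B3_synth_{i+1:02d}", s) for i, s in enumerate(b3)],
    )

    from genefamkit.domain_scan import load_bundled_profile
    from genefamkit.subfamilies import reference_records

    profile = load_bundled_profile("AP2")
    refs = reference_records(profile)
    write_fasta(
        DATA / "erf_clade_references_synthetic.fasta",
        [(f"{name} subfamily={label}", seq) for name, label, seq in refs],
    )
    print("wrote fixtures to", DATA)


if __name__ == "__main__":
    main()
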