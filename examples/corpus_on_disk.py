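"""Round-trip a corpus through the on-disk formats, then run the CLI path.

Writes a synthetic corpus (ASCII PSSMs, manifest TSV, attribute-scale TSV)
to a temporary directory, reads everything back through the format layer, and
reports the shape of the resulting feature matrix — the same flow the
``pssmloc extract`` command drives from the shell.
"""

import tempfile
from pathlib import Path

import pssmloc as pl

spec = pl.FixtureSpec(
    n_classes=2, samples_per_class=5, length_range=(30, 60), class_signal=0.8, seed=3
)

with tempfile.TemporaryDirectory() as tmp:
    corpus = pl.write_fixture_corpus(spec, Path(tmp) / "corpus")
    print(f"corpus written under {corpus}")

    manifest = pl.read_manifest(corpus / "manifest.tsv")
    samples = pl.expand_manifest(manifest)
    scale = pl.read_attribute_scale(corpus / "scale.tsv")
    pssms = [
        pl.parse_pssm(corpus / "pssm" / f"{pid}.pssm", protein_id=pid)
        for pid in samples.protein_ids
    ]
    print(f"parsed {len(pssms)} PSSMs; every row sums to 1 after renormalization")

    X, pids = pl.build_feature_matrix(pssms, samples, scale)
    print(f"feature matrix: {X.shape[0]} samples x {X.shape[1]} features")
    print(f"first columns: {list(X.columns[:3])} ...")
# Equivalent shell session:
#   pssmloc fixtures --spec spec.yaml --out corpus/
#   pssmloc extract --pssm-dir corpus/pssm --scale corpus/scale.tsv \
#       --manifest corpus/manifest.tsv --out matrix.csv
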