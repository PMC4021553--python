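#!/usr/bin/env python
"""Reproduce the published example-dataset AUCs from user-supplied data.

The benchmark datasets (fungal secretion, yeast expression) are hosted
externally and are not bundled here.  Given their FASTA and label files,
this script runs the same pipeline used for them: amino-acid composition
(optionally codon composition from an ORF FASTA), linear-kernel SVM, 10-fold
nested stratified cross-validation optimizing AUC.

Example:
    python scripts/reproduce_published.py \\
        --fasta proteins.fasta --labels labels.tsv --k 10 --seed 0
    python scripts/reproduce_published.py \\
        --fasta proteins.fasta --orf orfs.fasta --category codon_comp \\
        --labels labels.tsv
"""

import argparse
import sys

from protfeat.classify import ClassifierSpec, CVConfig, train_cv
from protfeat.featmat import FeatureMatrix
from protfeat.features import extract
from protfeat.seqdata import attach_orf, read_fasta, read_labels


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--fasta", required=True,
                    help="Protein FASTA file of the dataset")
    ap.add_argument("--labels", required=True,
                    help="Two-column TSV: protein id TAB class label")
    ap.add_argument("--orf", default=None,
                    help="ORF FASTA (needed for --category codon_comp)")
    ap.add_argument("--category", default="aac",
                    choices=["aac", "codon_comp"],
                    help="Feature category to evaluate (default: aac)")
    ap.add_argument("--k", type=int, default=10,
                    help="Cross-validation folds (default 10)")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args(argv)

    pset = read_fasta(args.fasta, "protein")
    if args.orf:
        attach_orf(pset, read_fasta(args.orf, "orf"))
    labeling = read_labels(args.labels, pset)
    fm = FeatureMatrix(extract(pset, args.category))
    result = train_cv(fm, labeling, ClassifierSpec("svm_linear"),
                      CVConfig(k_outer=args.k, seed=args.seed))
    print(f"category={args.category} n={len(pset)} k={args.k} "
          f"seed={args.seed}")
    for fr in result.folds:
        print(f"fold {fr.fold}: AUC={fr.auc:.4f} params={fr.chosen_params}")
    print(f"mean AUC = {result.mean_auc:.4f} "
          f"+/- {result.summary['auc_sd']:.4f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
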