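"""Aptamer-protein interaction prediction pipeline.

Sequence-derived encoders (k-mer / reverse-complement k-mer for aptamers,
AAC / PseAAC over physicochemical property groups for proteins), majority-
class neighborhood cleaning, random-forest feature selection, an MLP
classifier and fivefold cross-validated evaluation.
"""

from .aptamer import (
    FeatureVector,
    KmerSpec,
    canonical_kmer,
    count_canonical,
    kmer_vector,
    revc_kmer_vector,
    revcomp,
)
from .balancing import NCLParams, enn_misclassified, ncl_resample, random_undersample
from .evaluation import (
    ConfusionCounts,
    CVReport,
    MetricSet,
    PipelineSpec,
    confusion,
    cross_validate,
    metrics,
    roc_auc,
)
from .model import MLP, MLPConfig, baseline_fit_predict, build_mlp
from .protein import (
    PropertyTable,
    PseAACSpec,
    aac_vector,
    build_feature_matrix,
    load_property_table,
    pseaac_vector,
    standardize_properties,
    theta_tier,
)
from .selection import FeatureRanking, rank_features, select_top
from .seqio import (
    InteractionDataset,
    NucleotideSequence,
    ProteinSequence,
    read_fasta,
    read_pair_table,
    rna_to_dna,
    write_fasta,
)
from .synthetic import SyntheticParams, describe_signal, generate_dataset, preset_params

__version__ = "0.1.0"
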