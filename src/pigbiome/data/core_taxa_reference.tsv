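period	domain	phylum	class	order	family	genus	avg_counts
pre	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	Bacteroidaceae	Bacteroides	1701.22
pre	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	Prevotellaceae	Prevotella 9	379.38
pre	Bacteria	Firmicutes	Bacilli	Lactobacillales	Lactobacillaceae	Lactobacillus	235.67
pre	Bacteria	Firmicutes	Clostridia	Clostridiales	Clostridiaceae 1	Clostridium sensu stricto 1	12.26
pre	Bacteria	Firmicutes	Erysipelotrichia	Erysipelotrichales	Erysipelotrichaceae	Solobacterium	279.41
pre	Bacteria	Firmicutes	Negativicutes	Selenomonadales	Acidaminococcaceae	Phascolarctobacterium	716.12
pre	Bacteria	Firmicutes	Negativicutes	Selenomonadales	Veillonellaceae	Veillonella	127.03
pre	Bacteria	Fusobacteria	Fusobacteriia	Fusobacteriales	CFT112H7	uncultured bacterium	1607.82
pre	Bacteria	Fusobacteria	Fusobacteriia	Fusobacteriales	Fusobacteriaceae	Fusobacterium	2221.41
pre	Bacteria	Proteobacteria	Gammaproteobacteria	Enterobacteriales	Enterobacteriaceae	Escherichia-Shigella	6867.47
post	Bacteria	Actinobacteria	Coriobacteriia	Coriobacteriales	Coriobacteriaceae	Collinsella	71.94
post	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	Bacteroidaceae	Bacteroides	394.49
post	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	Bacteroidales S24-7 group	uncultured bacterium	837.35
post	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	Prevotellaceae	Alloprevotella	345.68
post	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	Prevotellaceae	Prevotella 1	637.91
post	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	Prevotellaceae	Prevotella 2	559.63
post	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	Prevotellaceae	Prevotella 7	2034.15
post	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	Prevotellaceae	Prevotella 9	1844.45
post	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	Prevotellaceae	Prevotellaceae NK3B31 group	451.12
post	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	Prevotellaceae	Prevotellaceae UCG-001	484.29
post	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	Prevotellaceae	uncultured	778.53
post	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	Rikenellaceae	Rikenellaceae RC9 gut group	639.62
post	Bacteria	Bacteroidetes	Bacteroidia	Bacteroidales	uncultured	uncultured bacterium	136.62
post	Bacteria	Firmicutes	Bacilli	Lactobacillales	Lactobacillaceae	Lactobacillus	327.90
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	[Ruminococcus] gauvreauii group	59.41
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Blautia	74.71
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Coprococcus 3	31.41
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Dorea	128.53
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Fusicatenibacter	98.26
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Lachnoclostridium	63.80
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Lachnospiraceae NK4A136 group	109.21
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Lachnospiraceae UCG-004	670.65
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Lachnospiraceae UCG-008	9.71
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Pseudobutyrivibrio	447.88
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Roseburia	734.65
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	uncultured	21.03
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	[Eubacterium] coprostanoligenes group	509.50
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	Faecalibacterium	588.15
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	Ruminiclostridium 9	184.18
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	Ruminococcaceae UCG-002	532.85
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	Ruminococcaceae UCG-005	112.04
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	Ruminococcaceae UCG-014	89.06
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	Subdoligranulum	147.72
post	Bacteria	Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	uncultured	18.94
post	Bacteria	Firmicutes	Erysipelotrichia	Erysipelotrichales	Erysipelotrichaceae	Catenibacterium	81.85
post	Bacteria	Firmicutes	Erysipelotrichia	Erysipelotrichales	Erysipelotrichaceae	Solobacterium	2971.06
post	Bacteria	Firmicutes	Negativicutes	Selenomonadales	Acidaminococcaceae	Acidaminococcus	555.88
post	Bacteria	Firmicutes	Negativicutes	Selenomonadales	Acidaminococcaceae	Phascolarctobacterium	719.92
post	Bacteria	Firmicutes	Negativicutes	Selenomonadales	Veillonellaceae	Anaerovibrio	1776.03
post	Bacteria	Firmicutes	Negativicutes	Selenomonadales	Veillonellaceae	Megasphaera	740.88
post	Bacteria	Fusobacteria	Fusobacteriia	Fusobacteriales	CFT112H7	uncultured bacterium	362.94
post	Bacteria	Proteobacteria	Epsilonproteobacteria	Campylobacterales	Helicobacteraceae	Helicobacter	597.76
post	Bacteria	Proteobacteria	Gammaproteobacteria	Enterobacteriales	Enterobacteriaceae	Escherichia-Shigella	943.12
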