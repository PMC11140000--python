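# Default functional-class vocabulary: 25 classes in priority order.
# Format: class label: comma-separated keywords (case-insensitive, whole-word).
# The two rule-assigned classes ("unknown conserved", "unknown") carry no
# keywords. Replace this file freely; the classifier validates that no
# keyword appears in two classes.
proteinase inhibitor: kunitz, serpin, cystatin, thyropin, macroglobulin, anticoagulant, ornithodorin, savignin, madanin, variegin, hirudin
proteinase: metalloprotease, metalloproteinase, reprolysin, trypsin, chymotrypsin, cathepsin, legumain, carboxypeptidase, aminopeptidase, peptidase, serine protease, cysteine protease, aspartic protease
lipocalin: lipocalin, moubatin, histamine binding protein, calycin
mucin: mucin, peritrophin, chitin binding protein
secreted: secreted, salivary protein, salivary gland protein, evasin, basic tail, 8.9 kDa family
immunity: defensin, lysozyme, microplusin, antimicrobial, ixoderin, thioester-containing protein, peptidoglycan recognition protein, hemocytin
oxidant metabolism: cytochrome P450, glutathione S-transferase, superoxide dismutase, catalase, peroxidase, thioredoxin, peroxiredoxin, sulfotransferase, carboxylesterase
storage: vitellogenin, hemelipoglycoprotein, ferritin, yolk protein, storage protein
extracellular matrix: collagen, laminin, fibronectin, cuticle protein, cuticular protein, dumpy, resilin
cytoskeletal: actin, myosin, tubulin, dynein, kinesin, tropomyosin, paramyosin, spectrin, troponin
protein synthesis machinery: ribosomal protein, ribosome, translation initiation factor, elongation factor, tRNA synthetase, tRNA ligase, ribosomal RNA
protein modification machinery: disulfide isomerase, prolyl isomerase, chaperone, chaperonin, heat shock protein, calreticulin, calnexin, oligosaccharyltransferase, glycosyltransferase
protein export machinery: signal recognition particle, translocon, coatomer, vesicle transport, syntaxin, SNARE, clathrin, adaptin, exocyst
proteasome machinery: proteasome, ubiquitin, ubiquitin-conjugating enzyme, cullin, SKP1
transcription machinery: RNA polymerase, spliceosome, splicing factor, small nuclear ribonucleoprotein, mediator complex, TATA-binding
transcription factor: transcription factor, homeobox, zinc finger, nuclear hormone receptor, bZIP, helix-loop-helix
signal transduction: kinase, phosphatase, GTPase, calmodulin, G protein, adenylate cyclase, arrestin, rhodopsin
metabolism, energy: ATP synthase, cytochrome c oxidase, NADH dehydrogenase, citrate synthase, succinate dehydrogenase, malate dehydrogenase, cytochrome b
metabolism, carbohydrate: glucosidase, galactosidase, amylase, trehalase, chitinase, glycogen, enolase, aldolase, glyceraldehyde-3-phosphate dehydrogenase
metabolism, lipid: lipase, phospholipase, fatty acid synthase, acyl-CoA, apolipoprotein, sterol carrier, desaturase
metabolism, amino acid: aminotransferase, transaminase, glutamine synthetase, arginase, glutamate dehydrogenase
metabolism, nucleotide: ribonucleotide reductase, adenylosuccinate, thymidylate, nucleoside, purine, pyrimidine
transporters and channels: transporter, channel, aquaporin, permease, symporter, antiporter, exchanger, innexin
unknown conserved:
unknown:
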