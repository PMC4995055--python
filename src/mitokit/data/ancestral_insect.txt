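# Canonical ancestral insect mitogenome gene order (Drosophila yakuba type),
# written with the same leucine-tRNA labels as the packaged whitefly table
# (trnL1 = UUR copy downstream of cox1, trnL2 = CUN copy downstream of nad1).
# The control region is omitted; 37 genes.
ancestral-insect: +trnI -trnQ +trnM +nad2 +trnW -trnC -trnY +cox1 +trnL1 +cox2 +trnK +trnD +atp8 +atp6 +cox3 +trnG +nad3 +trnA +trnR +trnN +trnS1 +trnE -trnF -nad5 -trnH -nad4 -nad4l +trnT -trnP +nad6 +cytb +trnS2 -nad1 -trnL2 -rrnL -trnV -rrnS
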