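# class	category	trigger substring (matched case-insensitively against keywords)
terminase	phage	terminase
capsid	phage	capsid
tail	phage	tail
spike	phage	spike
holin	phage	holin
portal	phage	portal
baseplate	phage	baseplate
partitioning	plasmid	para
partitioning	plasmid	parb
partitioning	plasmid	partition
conjugation	plasmid	conjugative transfer
conjugation	plasmid	tra protein
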