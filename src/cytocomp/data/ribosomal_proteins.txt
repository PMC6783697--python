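# Yeast 80S ribosomal proteins, family-level gene names (79 total:
# 33 small-subunit incl. ASC1, 46 large-subunit incl. P0/P1/P2).
RPS0
RPS1
RPS2
RPS3
RPS4
RPS5
RPS6
RPS7
RPS8
RPS9
RPS10
RPS11
RPS12
RPS13
RPS14
RPS15
RPS16
RPS17
RPS18
RPS19
RPS20
RPS21
RPS22
RPS23
RPS24
RPS25
RPS26
RPS27
RPS28
RPS29
RPS30
RPS31
ASC1
RPL1
RPL2
RPL3
RPL4
RPL5
RPL6
RPL7
RPL8
RPL9
RPL10
RPL11
RPL12
RPL13
RPL14
RPL15
RPL16
RPL17
RPL18
RPL19
RPL20
RPL21
RPL22
RPL23
RPL24
RPL25
RPL26
RPL27
RPL28
RPL29
RPL30
RPL31
RPL32
RPL33
RPL34
RPL35
RPL36
RPL37
RPL38
RPL39
RPL40
RPL41
RPL42
RPL43
RPP0
RPP1
RPP2
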