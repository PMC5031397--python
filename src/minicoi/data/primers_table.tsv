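name	sequence	orientation	note
SFF_145f	GTHACHGCYCAYGCHTTYGTAATAAT	forward	COI mini-barcode forward; pairs with SFF_351r for the 202 bp product
SFF_210f	GGAAAYTGRYTARTHCCHYTRATAATTGG	forward
SFF_348f	CMGTHTAYCCYCCYYTAGCAGG	forward
SFF_351f	CMGTHTAYCCHCCHYTAGCAGGAAA	forward
SFF_348r	GCATGDGCDAGRTTYCCNGC	reverse
SFF_351r	CTCCWGCRTGDGCWAGRTTTCC	reverse	COI mini-barcode reverse; pairs with SFF_145f for the 202 bp product
SFF_492r	ACDGATCAKACRAAYARKGGTG	reverse
BEGLCOIf	GGYGCYTGAGCHGGWATAGT	forward	580 bp COI barcoding pair (forward)
BEGLCOIr	ARRATDGGRTCYCCYCCTCC	reverse	580 bp COI barcoding pair (reverse)
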