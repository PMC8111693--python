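sequence	allele	note
AFSGPQACTRF	A*24:02	mpf_moiety
AFSGPQACTRFF	A*24:02	mpf_moiety
AIPFTYEQLDVLK	A*11:01	novel
ALACWGVRGSL	A*02:01	mpf_moiety
ALACWGVRGSLL	A*02:01	mpf_moiety
ALAQKNVKL	A*02:01	previously_reported
ALLATQMDRV	A*02:01	novel
ALLEVNKGHEM	A*02:01	novel
ALPTARPLL	A*24:02	novel
ATLIDRFVK	A*11:01	novel
AVALAQKNVK	A*11:01	novel
AVLPLTVAEV	A*02:01	novel
AVLPLTVAEVQK	A*11:01	previously_reported
EIDESLIFYK	A*11:01	novel
EIDESLIFYKK	A*11:01	novel
ELAVALAQK	A*11:01	novel
ESAEVLLPR	A*11:01	novel
ETLKALLEVNK	A*11:01	novel
EYFVKIQSF	A*24:02	mpf_moiety
FLNPDAFSGPQA	A*02:01	novel
FSGPQACTR	A*11:01	mpf_moiety
FTYEQLDVLK	A*11:01	novel
FYPGYLCSL	A*24:02	mpf_moiety
GLACDLPGRFV	A*02:01	mpf_moiety
GLQGGIPNGYLV	A*02:01	novel
GVLANPPNI	A*02:01	novel
GYPESVIQHL	A*24:02	mpf_moiety
IQHLGYLFLK	A*11:01	novel
KLLGPHVEGL	A*02:01	novel
KLLGPHVEGLK	A*11:01	novel
KLSTEQLRCL	A*02:01	novel
LLATQMDRV	A*02:01	novel
LLGPHVEGL	A*02:01	novel
LLSEADVRA	A*02:01	previously_reported
LLSEADVRAL	A*02:01	novel
LYPKARLAF	A*24:02	mpf_moiety
QVATLIDRFVK	A*11:01	novel
RLLPAALACWGV	A*02:01	novel
RLSEPPEDL	A*02:01	novel
RLSEPPEDLDAL	A*02:01	mpf_moiety
RQLDVLYPK	A*11:01	novel
RTDAVLPLTVAEVQK	A*11:01	novel
RVNAIPFTYEQLDVLK	A*11:01	novel
RVRELAVALAQKN	A*11:01	novel
SGPQACTRF	A*24:02	novel
SIPQGIVAAWR	A*11:01	mpf_moiety
SIPQGIVAAWRQR	A*11:01	mpf_moiety
SLGWVQPSR	A*11:01	novel
SLLSEADVRA	A*02:01	previously_reported
SLLSEADVRAL	A*02:01	novel
SLLSEADVRALGGL	A*02:01	novel
SLSPEELSSV	A*02:01	novel
SMDLATFMK	A*11:01	novel
STMDALRGL	A*02:01	novel
SVIQHLGYLFLK	A*11:01	novel
SVPPSSIWAVR	A*11:01	novel
SVSTMDALR	A*11:01	novel
TLAGETGQEAAPL	A*02:01	mpf_moiety
TMDALRGLLPV	A*02:01	mpf_moiety
TQMDRVNAI	A*02:01	novel
VIQHLGYLFLK	A*11:01	novel
VLDLSMQEA	A*02:01	novel
VLLPRLVSC	A*02:01	novel
VLPLTVAEV	A*02:01	previously_reported
VSMDLATFMK	A*11:01	novel
YGPPSTWSV	A*02:01	previously_reported
YLVLDLSMQEA	A*02:01	novel
YPESVIQHL	A*24:02	novel
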