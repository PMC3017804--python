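>seed01
EGAHYFEHMQCIL-PGGSSKLKRMRDDYQNMCHQDT-CAYADLIVFEFLYALGYKIYGQM
QFPSLLDKKEED-VLEVWEAG-CDMCCQVMWVHYRTDASPCDASMLPNLRWTWICTWTGS
EWNKEVPMNTIE-MG-MHYLWPPVDPTPYIAHDAVIDYTH
>seed02
EGQMFFESMQFIL-PGGSSNLKRMRDPYQLVCQQDM-IREEDLIVFEFLYVAGYKIYGQM
QFPSALDKKECD-VLENWEAG-CDMCQQVMWVHYREDHSPCDWWQAANLRWKWISTWTGS
SQNKEVPMNTIEQMG-MHLWWPPVDPTPYIAVDAVIDYTH
>seed03
EGAHYFESMQCIL-PGGSSKLKRMRDPYQNTCQQDM-IAYADSIVFGFLYALGYKIYGDM
QFPSLLDKKEDD-VLEVPEAG-CRMCQQVHWVHYREDAQPCDASMAANLRWKWICTWEGS
IQNKEVPMGTIE-MG-FHLLWPPVDPTTYIAHDAVIDYTH
>seed04
EGAHYFESMQCIL-PGGSSKLKRMRDPYQEVCQQMM-IAYADLIVFEFRYRLGYKIKGQM
QFPSLLDKKEDD-VLHKWEAG-CDMCNQVFWVHYREDASPCDVSMTANLRWKWICTWTGS
SQRKEEPMNTIE-YG-MHLLWPWVDPTPYIAHDAVIDYQH
>seed05
EGAHYFLSMQCIL-PGGSSMLKRMRDPYQNVCQQDMSIATADLPVFEFLYALGYKVYGQM
MLNSLTDKKEDA-VLEVWEAGACAHCQQVMWVHYREDAPPCDASHAANLRWKTICTWTGS
YQNKEVPMNTIE-MS-MHLLYPFVDPTDYIQHDAVIEYTH
>seed06
EGNHYFESMQWIL-PGGSKKLKRMWDPYQNVCQQDMSIACASLIVFEFLYALGYKIYGQM
QFPSLLDKKEDD-VSEVWEAG-CPMCQQVMWVHYREDASPCDGSMGANERWKWQCPFTGS
EQNKAVPMNTIE-MG-MHLLWPELDCTPYIAHDNVIDYTH
>seed07
EGMHNFESMQCIL-PGGSSKLWRYIDPYQNVCQQDMDIAYADDIVFEFWYALGYKIYGQM
QFPSLLDKKGDD-VLEEWEAG-CDMCQQVMQVLYRWDASPCDASMAQNLRWKWICTWTGS
SQNKSVPMNTIE-MGPDYLLWPPVDPTPAIAHDWVIVYTH
>seed08
EGAHYFESMWCIL-PGGSSKLKRMRDPYQNTCNQDM-IAYADLFVFEFLYALGYKVYGQM
QFPSLLDKKEIDQVLEVWEAGACDMCQQVMWCPYREDASPDDASMLANLRWKWICNWTGS
SQNKEVPMNTIE-MGQMHLLWPPVDPTPYRAHDAVIQQTH
>seed09
EGADNAESMLCIL-PGGSSKLKRMRDIYQNVCQQDMSIAYDDLIVFEFLYALGYKIYGQM
QFPSLLDKKEDD-VLEVWEAGACDMCWLVMWVHYVEDASECGASMAANLDWKWICTWTGS
SQNKEVPMWTIEVGGPMHLGWPPVDPTPYIAHDAVIDVTH
>seed10
GQSHYTESMQCINRPGGSRKLKRMRDPYQNVCQQDMSIAYADLIVFEFLYWLCYKIRGQM
QFPSLLDKKEDD-VLEVWEAG-CDMCQQVMWVHYREDASPCDASMAANLRWGWICTWTGS
SQNKEVPMNTIE-MG-MHAQWPSVDPTPYIAHDAWIDYTH
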