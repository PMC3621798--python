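>MbnB_syn role=MbnB synthetic model protein
MDYTCWWIWYKCQMFYRWAPCPRQKMHGRGRPHISSVSYCWYFYSMDNCHEEDLMETVCR
PIISPESQFRCCAGIVFPEYFCLHWHLFDCRPLWYEQFHDEFSWYPCQSKTCYDISEWLQ
QSPIRGLYKITVAGDQNMCAASMTRDRRWCTKANIDHDLWKAKMPNSDCPWYHMCKRHIL
QIVYCTETRSHMHQHGCWYYLMICKRWFTDAEDQMHHGDYIIQISEIWVWNWDMHCLGCM
KMYGPYPHSKCFQNDTDLWDKYAHHMYGPK
>MbnC_syn role=MbnC synthetic model protein
MSVEYHEDQRAFYRLLLHGVLQNCFTYYIPTMKAYVYARYMNRGLHHAQNKKPTVTCDFH
MDSKQTGSYDASPFDFAPAWHMYCCDDPQPMCDFGYKENKYIYCKICNCFDDKPHKPLNK
>MbnM_syn role=MbnM synthetic model protein
MFLWKDGGNIQEVLPRCWIKVQTCHRFSYTSHMDGPTEAWAMQGPICKDHSPGTFRGNFH
RMRADAAWIFDNTKGTCGKLHMGGYMMNCTAHRHKTMAMSFAHPIVQHPTWQNLMSWQTL
IMHSIPCVFQPFCNCYDCVFYDNQQHGPNMRSKRLMLSVWKSGHHLMYDHRNMWMENHRH
PYMAVWGQRPWSEGRRINHHWMDSDGVVSFQEYNHKHYYIYHVTRVLRNYLEQMRVRGKL
IFMVRFVIHQEGNEWHHHESIEGRCRWWVEYYMNFELNNHVRHLLYRHQWELFGRHPDKR
LFIIEPAPESFMLDQSFFWWNTHAVFLVNHRNQDEVSFQHWVYDFRHPESEEIHRFNWVQ
ISICGNTLWTYLTDQIQRPERNKKWDVPFERLVNSQPWQMMNARCGQEGGECMYQLIHIP
VWEPAIWLDVMKNTKTCWYD
>MbnT_syn role=MbnT synthetic model protein
MVWSARYVRNTVEIRSCQKTWVIPNLTFHTMMHDKFCMRFQAADFYDVIIHRLQVRAYVW
WMCDWAQKKAQQNTRFKAPMWSCFGFPDSDDWWDEYAVVRKFMFGMPFQSYKAVMSKYNI
ERMVGAGWEEPLDYKVAWKAEPGLIIDMKFTSLSEGEHHFGDSSMAEVYHDAIEPDMNMT
YWICSLWKHSTEVNIDLYRKRLKMCQECIQQLLKFKAYTCHCKLSPPVCSRASEWKWWAF
NIFCFVIHFRHIWGVRPASLERIDCMRLTKRSDMNMQYTWATANESNRFQLFVMCYTVEF
DGCIKGMYAIICCCTDVSPDWAEFDFVPRPDDMPIGDPIIMIIMHMICIYGEWHVNHMFY
MQHLPAHYHPNFPVSSPKVCVDFWCPQSCHKTFQHAPVVYIHFPTKMHVHMHMFQMSMWE
AVHREYEYWSWWARSMFLLHFAMMKDSDGHGKILVIDMQKFQWTKCTFNCLTAQDHETRV
DEINGEYTSTLITNTEMCRCAVQIIIMSKMFQKCTDAPDCYAMPPYDMHYYGEVHCEAYL
MCCICKVNSDPETVEDATVSLNPVSLFHVSIYNHGSIMRKACADRYMALSTVPRYSRLHE
HGLEFWGIAGKTADREFTLYYQDQREQHLNSSFFPENFLE
>MbnN_syn role=MbnN synthetic model protein
MIWFAFIVTPQAQSRTPEQNPDTFHWIDRFCSHYRDRQVHIDDYNRWFRNHRCMLAPGCY
QTYNYQLHIPRFGNHRWRDLGCIYPYEHAWCQFMQYFLDAPFPVCTGHKLEYWEMWTAEQ
YGKNTNQWYDKEMSYQWDSYESPKEWPSEEPSAYAIDVAPTTLCAWSVELRHQQNAFWDP
RGLEQDESSIIAMRMMGPGEGVYSSAPIWRFWHPDWYGPRLCYFLMHFSQDESGAYHFFD
WAEWFDSHCGRNYIPETYCQPCAIRGDWVMVRSDPSAQPHDIPMYDVSHIFTDAWKHGRN
GAPYEQFCGECPTAFGIFSYRCECDIIVSHERFINDYWHWKHKCSMYCSIQDQGDGWDWE
SDFNAQRAQWYIECESNPPE
>MbnS_syn role=MbnS synthetic model protein
MTWYCFSCFCTTRYFMCCWNMTHRTRAHNLSLYELMHFEGSEMQSEHWCQISIYRQRDDY
NVFTIYDVQQMCFYDNESSSKMIAATENWWRVSYKVTALCAPKPLRTTCIAAMALAVQIP
ACNHAERSIKDRHDKHDQRWRVSSMDVHSDDCQVMNDMAQQAPRDGFENPDYQHADIPNN
AVAHGATNVGTGVWRSCFVLMMRPMVMDWDLVCKNDHVFTWPSLAMNSYFTIPGSANRQF
HMEVYNLCWW
>MbnF_syn role=MbnF synthetic model protein
MRCCDSFFEAYGAKRRGEGWVVKKDCSGEHAYAETKWCLMMGFWNMHSMIAGHKIERCVI
PAMKYFFREIEITCKHRMCSFEGCYPRWHFMMIQHDMVYKWMKDGLIPHVVELWDEYTVM
GHFGSASAPEYPKIHIYEYMQMCNYMDMDHLRPNIVGTGTLAFYMLTQIRDNACYKGFWN
NDRSAPYANSKLAYCLKKQELQKEWIYLVCFTPRHVTKEKFMFPGFYPSEENMVHGGSSP
NNDPSNCSFGSYCGYLWAAWCDEPHCNMSAYQIDACPATTQEICCTDKEEHYYYLIMCVN
ICGENWWDYRVQAWEWLTYLVKYYYKKEADTKQARPPDQLPYCLIMECKSLWNMMWNHFD
YTGNMDSKAGGVNQKPLQRQ
>MbnI_syn role=MbnI synthetic model protein
MWSHEVCAYICGTQDIMCCFNCTRGEEYVFAKSCGLEFWQQQNGINYTFWPNNVNENTFF
NHEMFFLFNEQFWTFLPYFLKASFTYMWVYNQGDLRLKEADYVMYYGRQTAPICTMAFPC
ELREGAPDTRYVAWDMVRSIHVCEFMITKKFAKWTSASNIINDAATQTHC
>MbnR_syn role=MbnR synthetic model protein
MSQEPDFKPRKHEDTPHPDGRLWCWEASGYLMWIDEDSWGIDIYQFPWVDIRRYPPITDR
FMWGQAYTHNTNDCMEQGWKWLFAERTDCNCERHWFHYYAEKFNWNPSWSKEYCCCLQSE
AEDRSWIQYGHEHCFTMNQPKMDWKHMNQNWMIGVCPQKNWPSNMEGQCIGLNPVHNDHR
DNMDPVEVTTICSMWMNGMKFNYYPEEFIMNKSSMLQQFPDMPASMLDVCLVPLSQTTWV
HFNCPVVEDQQKLCMTDPLGPSGFFDSLMINQLFDHDFVSYYSEHRNFAPFRGKIWWWVW
>MbnP_syn role=MbnP synthetic model protein
MYDHTGIAQPFFDPKYQPCVWIYKTQYEVKFILFSYTNSYDQDQHKRPDFKCTSGFPFML
NFISNKYDISERMNALVILTSIDGQINWLDGNFPWTLWEQNQEWPKCGTTTGKSHFPFMN
CRIQGCSPYRLTQPVVANRAFMPRWDCNPWRSKEEPMMKYCPAHKLEMRAVNKHCFGEWD
NNGGPDLFPNWHKEWPTVEL
>MbnH_syn role=MbnH synthetic model protein
MNDMCPGRGGFVKFVEAQLHHPECHTSQHTMTKTDCFICSTWVSQHCRPTYNSMCNSCMR
YKETSRELPNCRLHKHDKMWSQLDRTHAHQEWCNREFHPIQRYMDQLHMGMRHKCLSDPW
ETQFCMELGCCMWMDLTTPCLQRSNCANWDSQDPNQQKRTQIANKQRYHCCVGGRWWHYP
DSQMVNNLINAYCCADWMWRCFNLLIVLCNRQWLTKFQVGSYQTVWVLRYWMTNYFKEPN
HTMWMVQHCLVAIGPRCQAEQGENAPDRLVIVWWDSDHTSNYVPATGNNKGTEQSTATRN
EKNTCLYCKQDGYQQWNYIECFTFNDTGEP
>mobility_syn role=mobility synthetic model protein
MLNISDKVHGCFFYVDSSVTIHYKDLTFKADTRRLLTFKCAQANISWWIFHNWEIIPRDW
KLFAKPKAILWARNHNKRWGNNWIGFDQTNNKGSPVQSHVWDNDVNMVIVLQHHGVWQEW
HRCHPLVIRAWPQMYEGLTEWDHWRNDYIAHWYAIWLFCHLNGTVGAAKIVPLPFAAQAT
AADKLQLTMQSKNSYAFTDASMNIAGKGNKECKFYNQCFY
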